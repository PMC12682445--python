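"""Within/between-class scoring, the Evaluation Index, and the 352-cell grid.

For one (pipeline, metric) scheme the normalized pair similarities are
averaged over same-class pairs (within) and different-class pairs
(between); the Evaluation Index

    index = (within + 1 - between) / 2

lies in [0, 1] and rewards compact, well-separated classes.  The full grid
crosses all 32 pipelines with all 11 metrics (352 schemes); schemes whose
metric preconditions fail on the processed data are recorded with
``status="failed"`` and a reason, never silently dropped, and are excluded
from selection and aggregates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConsistencyError, InputError, NirsimError
from .preprocess import PipelineSpec, apply_pipeline, enumerate_grid
from .simmetrics import METRIC_IDS, PairValue, pairwise_matrix
from .spectra import SpectralDataset

__all__ = [
    "SchemeResult",
    "pair_counts",
    "within_between",
    "evaluation_index",
    "run_grid",
    "select_schemes",
    "results_to_frame",
    "write_results",
    "plot_heatmap",
]


@dataclass
class SchemeResult:
    """Outcome of one (pipeline, metric) scheme."""

    pipeline_id: str
    metric_id: str
    within: float
    between: float
    index: float
    n_within_pairs: int
    n_between_pairs: int
    status: str = "ok"
    reason: str = ""


def _labels_mapping(labels) -> Mapping[str, str]:
    if isinstance(labels, Mapping):
        items = labels
    else:
        items = {i: lab for i, lab in enumerate(labels)}
    for key, lab in items.items():
        if lab is None or lab == "":
            raise InputError(f"sample {key!r} is unlabeled")
    return items


def pair_counts(labels) -> tuple[int, int]:
    """Unordered within-class and between-class pair counts.

    ``labels`` is a mapping sample_id -> class label or a plain sequence of
    labels.  n_within = sum_k C(n_k, 2); n_between = C(N, 2) - n_within."""
    items = _labels_mapping(labels)
    n = len(items)
    if n < 2:
        raise InputError("need at least 2 labeled samples")
    sizes = Counter(items.values())
    n_within = sum(math.comb(k, 2) for k in sizes.values())
    return n_within, math.comb(n, 2) - n_within


def within_between(
    pairs: Iterable[PairValue], labels: Mapping[str, str]
) -> tuple[float | None, float | None]:
    """Mean normalized similarity over same-class and different-class pairs.

    The pair batch must cover all C(N,2) unordered pairs of the labeled
    samples, already normalized.  A side with zero pairs is returned as
    ``None`` (undefined), not 0."""
    labels = _labels_mapping(labels)
    pairs = list(pairs)
    n = len(labels)
    expected = math.comb(n, 2)
    seen = set()
    w_sum = w_n = b_sum = b_n = 0
    for p in pairs:
        if p.normalized is None:
            raise InputError(f"pair ({p.id_a!r}, {p.id_b!r}) is not normalized")
        if p.id_a not in labels or p.id_b not in labels:
            raise ConsistencyError(
                f"pair ({p.id_a!r}, {p.id_b!r}) references an unlabeled sample"
            )
        key = (p.id_a, p.id_b)
        if key in seen:
            raise ConsistencyError(f"duplicate pair {key}")
        seen.add(key)
        if labels[p.id_a] == labels[p.id_b]:
            w_sum += p.normalized
            w_n += 1
        else:
            b_sum += p.normalized
            b_n += 1
    if len(seen) != expected:
        raise ConsistencyError(
            f"pair batch covers {len(seen)} pairs, expected C({n},2) = {expected}"
        )
    within = w_sum / w_n if w_n else None
    between = b_sum / b_n if b_n else None
    return within, between


def evaluation_index(within: float, between: float) -> float:
    """(within + 1 - between) / 2 — in [0, 1]; increases with within-class
    similarity and decreases with between-class similarity."""
    if not (0.0 <= within <= 1.0):
        raise InputError(f"within must be in [0,1], got {within}")
    if not (0.0 <= between <= 1.0):
        raise InputError(f"between must be in [0,1], got {between}")
    return (within + 1.0 - between) / 2.0


def run_grid(
    dataset: SpectralDataset,
    pipelines: Sequence[PipelineSpec] | None = None,
    metrics: Sequence[str] | None = None,
) -> list[SchemeResult]:
    """Evaluate every (pipeline, metric) scheme on a labeled dataset.

    Defaults to the full 32 x 11 = 352 grid.  Each result chains
    apply_pipeline -> pairwise_matrix (with batch normalization) ->
    within_between -> evaluation_index.  Results come back in deterministic
    order (pipelines outer, metrics inner)."""
    if pipelines is None:
        pipelines = enumerate_grid()
    if metrics is None:
        metrics = list(METRIC_IDS)
    labels = dict(dataset.labels)
    if set(labels) != set(dataset.sample_ids):
        missing = sorted(set(dataset.sample_ids) - set(labels))
        raise InputError(f"unlabeled sample(s): {missing}")
    n_within, n_between = pair_counts(labels)
    if len(set(labels.values())) < 2:
        raise InputError("need at least 2 classes")
    if n_within == 0:
        raise InputError("need at least one class with >= 2 samples")

    results: list[SchemeResult] = []
    for spec in pipelines:
        try:
            processed = apply_pipeline(dataset, spec)
            pipeline_error: NirsimError | None = None
        except NirsimError as exc:
            processed, pipeline_error = None, exc
        for metric_id in metrics:
            if pipeline_error is not None:
                results.append(
                    SchemeResult(
                        spec.id, metric_id, math.nan, math.nan, math.nan,
                        n_within, n_between, status="failed",
                        reason=str(pipeline_error),
                    )
                )
                continue
            try:
                pairs = pairwise_matrix(processed, metric_id)
                within, between = within_between(pairs, labels)
                idx = evaluation_index(within, between)
                results.append(
                    SchemeResult(
                        spec.id, metric_id, within, between, idx,
                        n_within, n_between,
                    )
                )
            except NirsimError as exc:
                results.append(
                    SchemeResult(
                        spec.id, metric_id, math.nan, math.nan, math.nan,
                        n_within, n_between, status="failed", reason=str(exc),
                    )
                )
    return results


def select_schemes(
    results: Iterable[SchemeResult],
    within_min: float = 0.9,
    between_max: float = 0.7,
) -> list[SchemeResult]:
    """Schemes with within >= within_min and between < between_max, sorted
    by index descending (ties broken by pipeline id, then metric id).
    Failed schemes are never selected; the result may be empty."""
    survivors = [
        r
        for r in results
        if r.status == "ok" and r.within >= within_min and r.between < between_max
    ]
    survivors.sort(key=lambda r: (-r.index, r.pipeline_id, r.metric_id))
    return survivors


def results_to_frame(results: Iterable[SchemeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pipeline_id": r.pipeline_id,
                "metric_id": r.metric_id,
                "within": r.within,
                "between": r.between,
                "index": r.index,
                "status": r.status,
                "n_within_pairs": r.n_within_pairs,
                "n_between_pairs": r.n_between_pairs,
            }
            for r in results
        ]
    )


def write_results(results: Iterable[SchemeResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def plot_heatmap(results: Iterable[SchemeResult], path: str | Path, value: str = "index"):
    """Optional pipelines x metrics heatmap (requires matplotlib).

    Failed cells are left blank (NaN)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = results_to_frame(results)
    pivot = frame.pivot(index="pipeline_id", columns="metric_id", values=value)
    fig, ax = plt.subplots(figsize=(0.8 * pivot.shape[1] + 2, 0.25 * pivot.shape[0] + 2))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=value)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
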