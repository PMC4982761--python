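"""Expression tiering, differential-expression filtering, and read-through calls.

The decision rules mirror a threshold-based knockdown-vs-control analysis:

* genes are tiered by control body FPKM (High > 500; Middle 100-500;
  Low 10-100; below 10 counts as not expressed);
* a gene list filter keeps genes with |ln fold change| > 0.2 in body
  expression;
* read-through RNA is called changed when the replicate-averaged fold of
  downstream-window FPKM exceeds 1.4 (up) or falls below 0.5 (down),
  restricted to genes whose read-through FPKM exceeds 0.5 in at least one
  condition;
* genes with an expressed same-strand neighbour inside the downstream
  window are excluded outright, since their window signal cannot be
  attributed to read-through.

Tier boundaries at the shared endpoints are resolved as Low = [10, 100],
Middle = (100, 500], High = (500, inf), preserving the strict ">" of the
High definition. Fold changes are pseudocount-stabilised with a small
epsilon in FPKM units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import GeneModel, downstream_window

logger = logging.getLogger(__name__)

CALLS = ("up", "down", "unchanged", "excluded_overlap", "excluded_low")

CALL_COLUMNS = [
    "gene_id", "tier", "ctrl_rt_fpkm", "trt_rt_fpkm", "fold_change", "call"
]


@dataclass
class ClassifierConfig:
    min_rt_fpkm: float = 0.5
    fc_up: float = 1.4
    fc_down: float = 0.5
    ln_fc: float = 0.2
    tier_bounds: tuple[float, float, float] = (10.0, 100.0, 500.0)
    pseudocount: float = 0.1
    window_bp: int = 5000
    min_neighbor_fpkm: float = 1.0
    neighbor_same_strand_only: bool = True
    # "window-contains-neighbor": drop genes whose downstream window holds an
    # expressed gene (default). "inside-neighbor-window": additionally drop
    # genes lying inside another expressed gene's downstream window.
    exclusion_mode: str = "window-contains-neighbor"

    def __post_init__(self) -> None:
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_rt_fpkm < 0 or self.ln_fc < 0:
            raise ValueError("thresholds must be >= 0")
        lo, mid, hi = self.tier_bounds
        if not 0 < lo < mid < hi:
            raise ValueError("tier_bounds must be increasing and positive")
        if self.exclusion_mode not in ("window-contains-neighbor", "inside-neighbor-window"):
            raise ValueError(f"unknown exclusion_mode {self.exclusion_mode!r}")


def assign_tier(
    body_fpkm: float, bounds: tuple[float, float, float] = (10.0, 100.0, 500.0)
) -> str:
    """High > hi; Middle (mid, hi]; Low [lo, mid]; else No."""
    if body_fpkm < 0:
        raise ValueError("body_fpkm must be >= 0")
    lo, mid, hi = bounds
    if body_fpkm > hi:
        return "High"
    if body_fpkm > mid:
        return "Middle"
    if body_fpkm >= lo:
        return "Low"
    return "No"


def diff_expression_filter(
    ctrl_fpkm: float, trt_fpkm: float, ln_fc: float = 0.2, pseudocount: float = 0.1
) -> str:
    """'up' / 'down' / 'stable' by the natural-log fold change of body FPKM."""
    if ctrl_fpkm < 0 or trt_fpkm < 0:
        raise ValueError("FPKM must be >= 0")
    lfc = np.log((trt_fpkm + pseudocount) / (ctrl_fpkm + pseudocount))
    if lfc > ln_fc:
        return "up"
    if lfc < -ln_fc:
        return "down"
    return "stable"


def has_expressed_downstream_neighbor(
    gene: GeneModel,
    models: Sequence[GeneModel],
    max_body_fpkm: Mapping[str, float],
    window_bp: int,
    min_neighbor_fpkm: float = 1.0,
    same_strand_only: bool = True,
    chrom_length: int | None = None,
) -> bool:
    """True when another expressed gene's span intersects the downstream window.

    ``max_body_fpkm`` maps gene_id to the largest condition-mean body FPKM,
    so a neighbour expressed in either condition triggers the exclusion.
    """
    window = downstream_window(gene, window_bp, chrom_length)
    if window is None:
        return False
    for other in models:
        if other.gene_id == gene.gene_id or other.span.chrom != window.chrom:
            continue
        if same_strand_only and other.span.strand != gene.span.strand:
            continue
        if other.span.start < window.end and other.span.end > window.start:
            if max_body_fpkm.get(other.gene_id, 0.0) >= min_neighbor_fpkm:
                return True
    return False


@dataclass(frozen=True)
class ReadthroughCall:
    gene_id: str
    ctrl_rt_fpkm: float
    trt_rt_fpkm: float
    fold_change: float
    call: str


def call_readthrough(
    ctrl_rt_fpkm: Sequence[float],
    trt_rt_fpkm: Sequence[float],
    config: ClassifierConfig | None = None,
    gene_id: str = "",
) -> ReadthroughCall:
    """Classify one gene's read-through change from per-replicate FPKM vectors.

    With equal replicate counts the fold change is the mean of per-pair
    (treatment_i + eps) / (control_i + eps) ratios; otherwise each treatment
    replicate is compared against the control replicate mean. The expression
    filter uses the larger condition mean, so read-through arising only in
    the treatment remains callable.
    """
    config = config or ClassifierConfig()
    ctrl = np.asarray(ctrl_rt_fpkm, dtype=float)
    trt = np.asarray(trt_rt_fpkm, dtype=float)
    if ctrl.size == 0 or trt.size == 0:
        raise ValueError("need at least one replicate per condition")
    eps = config.pseudocount
    if ctrl.size == trt.size:
        fold = float(np.mean((trt + eps) / (ctrl + eps)))
    else:
        fold = float(np.mean((trt + eps) / (ctrl.mean() + eps)))
    ctrl_mean, trt_mean = float(ctrl.mean()), float(trt.mean())
    if max(ctrl_mean, trt_mean) <= config.min_rt_fpkm:
        call = "excluded_low"
    elif fold > config.fc_up:
        call = "up"
    elif fold < config.fc_down:
        call = "down"
    else:
        call = "unchanged"
    return ReadthroughCall(gene_id, ctrl_mean, trt_mean, fold, call)


def classify_all(
    models: Sequence[GeneModel],
    quants: pd.DataFrame,
    control: str,
    treatment: str,
    config: ClassifierConfig | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Per-gene read-through calls for one control/treatment pair.

    Overlap exclusion is applied before any fold-change call. Tiers are
    assigned from the control-condition mean body FPKM. Returns one row per
    gene in annotation order.
    """
    config = config or ClassifierConfig()
    conditions = set(quants["condition"].unique())
    for label in (control, treatment):
        if label not in conditions:
            raise ValueError(f"condition {label!r} not present in quantification table")

    by_gene_cond = quants.groupby(["gene_id", "condition"], sort=False)
    mean_body = by_gene_cond["body_fpkm"].mean().unstack(fill_value=0.0)
    max_body = mean_body[[control, treatment]].max(axis=1).to_dict()

    excluded = _excluded_overlap(models, max_body, config, chrom_length)

    rt = quants.pivot_table(
        index="gene_id", columns=["condition", "replicate"],
        values="rt_fpkm", sort=False,
    )
    rows = []
    n_calls = {c: 0 for c in CALLS}
    for m in models:
        ctrl_vec = rt.loc[m.gene_id, control].to_numpy(dtype=float)
        trt_vec = rt.loc[m.gene_id, treatment].to_numpy(dtype=float)
        ctrl_vec = ctrl_vec[~np.isnan(ctrl_vec)]
        trt_vec = trt_vec[~np.isnan(trt_vec)]
        tier = assign_tier(float(mean_body.loc[m.gene_id, control]), config.tier_bounds)
        res = call_readthrough(ctrl_vec, trt_vec, config, gene_id=m.gene_id)
        call = "excluded_overlap" if m.gene_id in excluded else res.call
        n_calls[call] += 1
        rows.append(
            {
                "gene_id": m.gene_id,
                "tier": tier,
                "ctrl_rt_fpkm": res.ctrl_rt_fpkm,
                "trt_rt_fpkm": res.trt_rt_fpkm,
                "fold_change": res.fold_change,
                "call": call,
            }
        )
    logger.info(
        "read-through calls: %d up, %d down, %d unchanged, %d excluded (overlap), "
        "%d excluded (low)",
        n_calls["up"], n_calls["down"], n_calls["unchanged"],
        n_calls["excluded_overlap"], n_calls["excluded_low"],
    )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _excluded_overlap(
    models: Sequence[GeneModel],
    max_body: Mapping[str, float],
    config: ClassifierConfig,
    chrom_length: int | None,
) -> set[str]:
    excluded = set()
    for m in models:
        if has_expressed_downstream_neighbor(
            m, models, max_body, config.window_bp,
            config.min_neighbor_fpkm, config.neighbor_same_strand_only, chrom_length,
        ):
            excluded.add(m.gene_id)
    if config.exclusion_mode == "inside-neighbor-window":
        for m in models:
            for other in models:
                if other.gene_id == m.gene_id:
                    continue
                if config.neighbor_same_strand_only and other.span.strand != m.span.strand:
                    continue
                if max_body.get(other.gene_id, 0.0) < config.min_neighbor_fpkm:
                    continue
                w = downstream_window(other, config.window_bp, chrom_length)
                if w is not None and m.span.chrom == w.chrom and (
                    m.span.start < w.end and m.span.end > w.start
                ):
                    excluded.add(m.gene_id)
                    break
    return excluded
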