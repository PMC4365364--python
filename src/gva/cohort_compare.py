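"""Two-cohort genetic-vector comparison: alignment, Ω-stratification,
consistency selection, contrast matrices and the end-to-end pipeline.

A finding in one cohort is credible when the independent cohort shows an
effect in the same direction and of comparable strength. The machinery here
stratifies the GVs common to both cohorts into four classes by the sign of
the effect (Ω11 risk in both, Ω22 protective in both, Ω12/Ω21 inconsistent),
keeps only GVs beyond the cohort-specific 5%-tail OR thresholds in *both*
cohorts, and summarizes the genotype content of the surviving "contrast"
GVs as count-weighted averages of their index matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from gva.genotype_io import CohortGenotypes, MarkerPanel
from gva.gv_core import (
    GeneticVector,
    GVTable,
    build_gv_table,
    crop,
    index_matrix,
)
from gva.gv_stats import (
    ZeroGVStatus,
    classify_zero,
    mean_or,
    odds_ratio,
    or_distribution,
    or_thresholds,
    tail_prob,
)

__all__ = [
    "AlignResult",
    "OmegaPartition",
    "GVConsistencyRecord",
    "ContrastSelection",
    "ContrastMatrices",
    "ZeroGVMatrices",
    "GVAReport",
    "align_cohorts",
    "stratify_omega",
    "select_consistent",
    "contrast_average",
    "contrast_matrices",
    "zero_gv_matrices",
    "run_gva",
]

Group = Literal["h", "s"]


@dataclass(frozen=True)
class AlignResult:
    """GV sets shared and specific to each cohort, with individual counts."""

    common: list[GeneticVector]
    a_only: list[GeneticVector]
    b_only: list[GeneticVector]
    n_common: tuple[int, int]  # individuals in common GVs (cohort a, cohort b)
    n_a_only: int
    n_b_only: int


def align_cohorts(a: GVTable, b: GVTable) -> AlignResult:
    """Split the two cohorts' GV sets into common / a-only / b-only."""
    if a.panel.names != b.panel.names:
        raise ValueError(f"panels differ: {a.panel.names} vs {b.panel.names}")
    set_a, set_b = set(a.entries), set(b.entries)
    common = sorted(set_a & set_b)
    a_only = sorted(set_a - set_b)
    b_only = sorted(set_b - set_a)
    return AlignResult(
        common,
        a_only,
        b_only,
        (
            sum(a.entries[gv].n_t for gv in common),
            sum(b.entries[gv].n_t for gv in common),
        ),
        sum(a.entries[gv].n_t for gv in a_only),
        sum(b.entries[gv].n_t for gv in b_only),
    )


@dataclass(frozen=True)
class OmegaPartition:
    """Four-way split of common non-zero GVs by effect direction.

    Membership is by the sign of (OR_a − 1, OR_b − 1); an OR of exactly 1
    counts as the protective (< 1) side, so the risk classes are strict.
    ``boundary`` lists GVs where either OR equalled 1 exactly.
    """

    omega_11: list[GeneticVector]  # OR > 1 in both
    omega_12: list[GeneticVector]  # risk in a, protective in b
    omega_21: list[GeneticVector]  # protective in a, risk in b
    omega_22: list[GeneticVector]  # OR < 1 in both
    boundary: list[GeneticVector] = field(default_factory=list)

    def all_gvs(self) -> list[GeneticVector]:
        return sorted(self.omega_11 + self.omega_12 + self.omega_21 + self.omega_22)


def stratify_omega(
    common: Sequence[GeneticVector],
    or_a: dict[GeneticVector, float],
    or_b: dict[GeneticVector, float],
) -> OmegaPartition:
    buckets: dict[tuple[int, int], list[GeneticVector]] = {
        (1, 1): [], (1, 2): [], (2, 1): [], (2, 2): []
    }
    boundary: list[GeneticVector] = []
    for gv in sorted(common):
        ra, rb = or_a[gv], or_b[gv]
        if not (math.isfinite(ra) and math.isfinite(rb)):
            raise ValueError(f"GV {gv}: non-finite OR; exclude zero GVs before stratifying")
        if ra == 1.0 or rb == 1.0:
            boundary.append(gv)
        key = (1 if ra > 1 else 2, 1 if rb > 1 else 2)
        buckets[key].append(gv)
    return OmegaPartition(
        buckets[(1, 1)], buckets[(1, 2)], buckets[(2, 1)], buckets[(2, 2)], boundary
    )


@dataclass(frozen=True)
class GVConsistencyRecord:
    """Per-GV, per-cohort evidence backing a selection decision."""

    gv: GeneticVector
    n_h: int
    n_s: int
    or_exp: float
    mean_rand_or: float
    or_lower_tr: float
    or_upper_tr: float
    p_tail: float  # upper tail for risk candidates, lower tail for protective

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_tail) if self.p_tail > 0 else math.inf


@dataclass(frozen=True)
class ContrastSelection:
    """Consistency-selected risk and protective GV sets with their evidence."""

    risk_set: list[GeneticVector]
    protective_set: list[GeneticVector]
    records_a: dict[GeneticVector, GVConsistencyRecord]
    records_b: dict[GeneticVector, GVConsistencyRecord]
    alpha: float


def _consistency_record(
    table: GVTable, gv: GeneticVector, alpha: float, side: Literal["upper", "lower"]
) -> GVConsistencyRecord:
    e = table.entries[gv]
    dist = or_distribution(table.N_h, table.N_s, e.n_t)
    or_exp = odds_ratio(e, table.N_h, table.N_s)
    thr = or_thresholds(dist, alpha)
    return GVConsistencyRecord(
        gv=gv,
        n_h=e.n_h,
        n_s=e.n_s,
        or_exp=or_exp,
        mean_rand_or=mean_or(dist) if e.n_t >= 2 else math.nan,
        or_lower_tr=thr.or_lower_tr,
        or_upper_tr=thr.or_upper_tr,
        p_tail=tail_prob(dist, or_exp, side),
    )


def select_consistent(
    partition: OmegaPartition,
    table_a: GVTable,
    table_b: GVTable,
    alpha: float = 0.05,
) -> ContrastSelection:
    """Keep Ω11 GVs beyond the upper α-threshold in both cohorts (risk set)
    and Ω22 GVs beyond the lower α-threshold in both cohorts (protective).

    Each cohort's threshold comes from its own randomized-OR distribution
    at that cohort's (N_h, N_s, n_t) — the protective criterion mirrors the
    risk one on the lower tail rather than using a fixed 1/OR_upper.
    """
    records_a: dict[GeneticVector, GVConsistencyRecord] = {}
    records_b: dict[GeneticVector, GVConsistencyRecord] = {}

    risk: list[GeneticVector] = []
    for gv in partition.omega_11:
        ra = _consistency_record(table_a, gv, alpha, "upper")
        rb = _consistency_record(table_b, gv, alpha, "upper")
        records_a[gv], records_b[gv] = ra, rb
        if ra.or_exp > ra.or_upper_tr and rb.or_exp > rb.or_upper_tr:
            risk.append(gv)

    protective: list[GeneticVector] = []
    for gv in partition.omega_22:
        ra = _consistency_record(table_a, gv, alpha, "lower")
        rb = _consistency_record(table_b, gv, alpha, "lower")
        records_a[gv], records_b[gv] = ra, rb
        if ra.or_exp < ra.or_lower_tr and rb.or_exp < rb.or_lower_tr:
            protective.append(gv)

    return ContrastSelection(sorted(risk), sorted(protective), records_a, records_b, alpha)


def contrast_average(
    table: GVTable, gvs: Iterable[GeneticVector], group: Group
) -> np.ndarray:
    """Count-weighted average of index matrices over a GV selection.

    Weights are n_ν^α / Σ n_ν^α over the selection only (not the cohort
    total), so columns of the result sum to 1.
    """
    gvs = sorted(gvs)
    if not gvs:
        raise ValueError("empty GV selection")
    weights = np.array(
        [
            table.entries[gv].n_h if group == "h" else table.entries[gv].n_s
            for gv in gvs
        ],
        dtype=float,
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} has no individuals in the selection")
    m = np.zeros((3, len(table.panel)))
    for w, gv in zip(weights, gvs):
        if w:
            m += w * index_matrix(gv)
    return m / total


@dataclass(frozen=True)
class ContrastMatrices:
    """Case and control genotype-content matrices of a selection, and their
    difference (positive cells point toward disease)."""

    freq_case: np.ndarray
    freq_ctrl: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.freq_case - self.freq_ctrl


def contrast_matrices(table: GVTable, gvs: Iterable[GeneticVector]) -> ContrastMatrices:
    gvs = list(gvs)
    return ContrastMatrices(
        freq_case=contrast_average(table, gvs, "s"),
        freq_ctrl=contrast_average(table, gvs, "h"),
    )


@dataclass(frozen=True)
class ZeroGVMatrices:
    """Weighted index-matrix averages over the zero-GV subsets of a cohort.

    ``c_ss``/``c_sh`` average the solely-sick / solely-healthy GVs with
    weights proportional to their (case resp. control) counts; either may
    be None when the subset is empty. ``diff`` is c_ss − c_sh when both
    exist.
    """

    c_ss: Optional[np.ndarray]
    c_sh: Optional[np.ndarray]
    ss_gvs: list[GeneticVector]
    sh_gvs: list[GeneticVector]

    @property
    def diff(self) -> Optional[np.ndarray]:
        if self.c_ss is None or self.c_sh is None:
            return None
        return self.c_ss - self.c_sh


def _zero_matrices_one(table: GVTable) -> ZeroGVMatrices:
    ss = [gv for gv, e in table.entries.items() if classify_zero(e) is ZeroGVStatus.SOLELY_SICK]
    sh = [gv for gv, e in table.entries.items() if classify_zero(e) is ZeroGVStatus.SOLELY_HEALTHY]
    c_ss = contrast_average(table, ss, "s") if ss else None
    c_sh = contrast_average(table, sh, "h") if sh else None
    return ZeroGVMatrices(c_ss, c_sh, sorted(ss), sorted(sh))


def zero_gv_matrices(
    table_a: GVTable, table_b: GVTable
) -> tuple[ZeroGVMatrices, ZeroGVMatrices, Optional[np.ndarray]]:
    """Zero-GV genotype-content matrices per cohort plus a cross-cohort
    consistency mask (True where the case-minus-control difference has the
    same sign in both cohorts); the mask is None when either cohort lacks
    a difference matrix."""
    za = _zero_matrices_one(table_a)
    zb = _zero_matrices_one(table_b)
    consistent = None
    if za.diff is not None and zb.diff is not None:
        consistent = np.sign(za.diff) == np.sign(zb.diff)
    return za, zb, consistent


@dataclass
class GVAReport:
    """Everything the nine-stage pipeline produces for one cohort pair."""

    panel: MarkerPanel
    table_a: GVTable
    table_b: GVTable
    alignment: AlignResult
    zero_a: list[GeneticVector]
    zero_b: list[GeneticVector]
    filtered_a: GVTable  # common, non-zero GVs; totals per `totals` policy
    filtered_b: GVTable
    partition: OmegaPartition
    selection: ContrastSelection
    risk_contrast_a: Optional[ContrastMatrices]
    risk_contrast_b: Optional[ContrastMatrices]
    protective_contrast_a: Optional[ContrastMatrices]
    protective_contrast_b: Optional[ContrastMatrices]
    zero_matrices: tuple[ZeroGVMatrices, ZeroGVMatrices, Optional[np.ndarray]]
    cropped: Optional[dict] = None


def run_gva(
    a: CohortGenotypes | GVTable,
    b: CohortGenotypes | GVTable,
    panel: MarkerPanel | None = None,
    alpha: float = 0.05,
    totals: Literal["raw", "filtered"] = "filtered",
    crop_keep: Optional[Sequence[int]] = None,
) -> GVAReport:
    """Run the full two-cohort GVA pipeline.

    Stages: build GV tables → align cohorts → set aside cohort-specific and
    zero GVs → per-GV exact statistics on the common non-zero set →
    Ω-stratification → both-cohort consistency selection at ``alpha`` →
    contrast genotype-content matrices → zero-GV matrices → optional
    crop-and-recompute of the contrast matrices on a marker subset.

    ``totals`` picks the cohort sizes entering the per-GV null
    distributions: "filtered" (default) uses the common non-zero subset
    totals, "raw" the full cohort sizes.
    """
    if isinstance(a, GVTable):
        table_a = a
        panel = a.panel
    else:
        if panel is None:
            raise ValueError("panel required when passing raw cohorts")
        table_a = build_gv_table(a, panel)
    table_b = b if isinstance(b, GVTable) else build_gv_table(b, panel)

    alignment = align_cohorts(table_a, table_b)

    zero_a = sorted(
        gv for gv in alignment.common
        if classify_zero(table_a.entries[gv]) is not ZeroGVStatus.NONE
    )
    zero_b = sorted(
        gv for gv in alignment.common
        if classify_zero(table_b.entries[gv]) is not ZeroGVStatus.NONE
    )
    keep = [gv for gv in alignment.common if gv not in set(zero_a) | set(zero_b)]

    filtered_a = table_a.restrict(keep, retotal=(totals == "filtered"))
    filtered_b = table_b.restrict(keep, retotal=(totals == "filtered"))

    or_a = {gv: odds_ratio(filtered_a.entries[gv], filtered_a.N_h, filtered_a.N_s) for gv in keep}
    or_b = {gv: odds_ratio(filtered_b.entries[gv], filtered_b.N_h, filtered_b.N_s) for gv in keep}
    partition = stratify_omega(keep, or_a, or_b)
    selection = select_consistent(partition, filtered_a, filtered_b, alpha)

    def _pair(gvs: list[GeneticVector]):
        if not gvs:
            return None, None
        return (
            contrast_matrices(filtered_a, gvs),
            contrast_matrices(filtered_b, gvs),
        )

    risk_a, risk_b = _pair(selection.risk_set)
    prot_a, prot_b = _pair(selection.protective_set)

    report = GVAReport(
        panel=panel,
        table_a=table_a,
        table_b=table_b,
        alignment=alignment,
        zero_a=zero_a,
        zero_b=zero_b,
        filtered_a=filtered_a,
        filtered_b=filtered_b,
        partition=partition,
        selection=selection,
        risk_contrast_a=risk_a,
        risk_contrast_b=risk_b,
        protective_contrast_a=prot_a,
        protective_contrast_b=prot_b,
        zero_matrices=zero_gv_matrices(table_a, table_b),
    )

    if crop_keep is not None and selection.risk_set:
        ca = crop(filtered_a.restrict(selection.risk_set, retotal=True), crop_keep)
        cb = crop(filtered_b.restrict(selection.risk_set, retotal=True), crop_keep)
        report.cropped = {
            "keep": list(crop_keep),
            "risk_a": contrast_matrices(ca, ca.gvs()),
            "risk_b": contrast_matrices(cb, cb.gvs()),
        }
    return report
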