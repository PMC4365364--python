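"""Bundled summary data from a published two-cohort rheumatoid arthritis study.

The study genotyped six SNPs in the HTR2A locus plus the HLA-DRB1
shared-epitope (SE) copy number in two independent case-control cohorts —
a Swedish one (EIRA) and a North American one (NARAC) — and published the
cross-cohort-consistent contrast GV groups with their per-cohort control
and case counts. Those summary counts, together with the panel's state
alphabets and the worked single-GV example parameters, are enough to
exercise every statistic in this package without the (unavailable) raw
individual-level data.
"""

from __future__ import annotations

from gva.genotype_io import MarkerDef, MarkerKind, MarkerPanel
from gva.gv_core import GVTable

__all__ = [
    "rheumatoid_arthritis_panel",
    "risk_contrast_tables",
    "protective_contrast_tables",
    "FILTERED_TOTALS",
    "SINGLE_GV_EXAMPLE",
]


def rheumatoid_arthritis_panel() -> MarkerPanel:
    """The 7-marker HTR2A + SE panel with its published state alphabets."""
    snp = MarkerKind.SNP
    return MarkerPanel(
        (
            MarkerDef("rs6314", snp, ("CC", "CT", "TT")),
            MarkerDef("rs977003", snp, ("AA", "AC", "CC")),
            MarkerDef("rs1328674", snp, ("CC", "CT", "TT")),
            MarkerDef("rs2070037", snp, ("CC", "CT", "TT")),
            MarkerDef("rs6313", snp, ("AA", "AG", "GG")),
            MarkerDef("rs6311", snp, ("CC", "CT", "TT")),
            MarkerDef("SE", MarkerKind.CATEGORICAL, ("No", "Single", "Double")),
        )
    )


# Post-filter cohort totals (common, non-zero GV subset): {cohort: (N_h, N_s)}
FILTERED_TOTALS: dict[str, tuple[int, int]] = {
    "EIRA": (779, 1500),
    "NARAC": (866, 711),
}

# The published worked example: one risk GV group of 4 controls + 33 cases
# inside the filtered EIRA cohort; printed alongside it were the observed
# OR 4.3584, mean randomized OR 1.0929 and upper 5% threshold 1.9.
SINGLE_GV_EXAMPLE = {"n_h": 4, "n_s": 33, "N_h": 779, "N_s": 1500}

# Cross-cohort-consistent risk GV groups (OR above the upper 5% threshold
# in BOTH cohorts): (gv, (n_h, n_s) EIRA, (n_h, n_s) NARAC)
_RISK_ROWS = [
    ((1, 2, 1, 3, 3, 1, 3), (1, 16), (3, 15)),
    ((1, 1, 1, 3, 2, 2, 3), (6, 35), (7, 25)),
    ((1, 1, 1, 2, 2, 2, 3), (6, 35), (2, 17)),
    ((1, 2, 1, 3, 2, 2, 3), (9, 38), (9, 36)),
    ((1, 1, 1, 2, 3, 1, 3), (9, 47), (3, 19)),
    ((1, 2, 1, 2, 2, 2, 3), (4, 33), (4, 17)),
]

# Cross-cohort-consistent protective GV groups (below the lower threshold
# in both cohorts), same layout
_PROTECTIVE_ROWS = [
    ((1, 1, 1, 3, 2, 2, 1), (45, 47), (40, 1)),
    ((1, 1, 1, 2, 2, 2, 1), (40, 38), (34, 1)),
    ((1, 2, 1, 2, 2, 2, 1), (30, 33), (51, 1)),
    ((1, 2, 1, 3, 2, 2, 1), (57, 41), (65, 1)),
    ((2, 2, 1, 3, 2, 2, 1), (16, 5), (14, 1)),
    ((1, 2, 1, 3, 1, 3, 1), (25, 22), (42, 3)),
    ((1, 1, 1, 3, 3, 2, 1), (28, 28), (24, 1)),
    ((1, 1, 1, 3, 1, 3, 1), (11, 9), (21, 1)),
]


def _tables(rows, use_filtered_totals: bool) -> dict[str, GVTable]:
    panel = rheumatoid_arthritis_panel()
    out = {}
    for cohort, col in (("EIRA", 1), ("NARAC", 2)):
        counts = [(r[0], r[col][0], r[col][1]) for r in rows]
        if use_filtered_totals:
            N_h, N_s = FILTERED_TOTALS[cohort]
            out[cohort] = GVTable.from_counts(panel, counts, N_h=N_h, N_s=N_s)
        else:
            out[cohort] = GVTable.from_counts(panel, counts)
    return out


def risk_contrast_tables(use_filtered_totals: bool = True) -> dict[str, GVTable]:
    """The six published risk-consistent contrast GV groups per cohort.

    With ``use_filtered_totals`` the tables carry the filtered cohort totals
    (EIRA 779/1500, NARAC 866/711); otherwise totals are the selection sums.
    """
    return _tables(_RISK_ROWS, use_filtered_totals)


def protective_contrast_tables(use_filtered_totals: bool = True) -> dict[str, GVTable]:
    """The eight published protective-consistent contrast GV groups per cohort."""
    return _tables(_PROTECTIVE_ROWS, use_filtered_totals)
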