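"""Paired synthetic case-control cohorts with controlled GV structure.

The generator emulates what the real two-cohort data looked like: a modest
pool of distinct GVs with heavy-tailed (power-law) frequencies, most GVs
shared between cohorts, a handful of planted effect GVs with known odds
ratios, and optional "zero" GVs populated by one phenotype only. Controls
are drawn from the base GV frequencies; case frequencies are obtained by
reweighting each GV's control frequency by its planted odds and
renormalizing, so the planted OR is matched in expectation (exactly so in
the small-frequency regime where odds ≈ probability ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from gva.genotype_io import CohortGenotypes, MarkerDef, MarkerKind, MarkerPanel, Phenotype
from gva.gv_core import GeneticVector, GVTable

__all__ = ["SimConfig", "generate_pair", "synthetic_panel", "write_fixture_tables"]

_SNP_ALPHABETS = [
    ("AA", "AC", "CC"),
    ("CC", "CT", "TT"),
    ("GG", "GT", "TT"),
    ("AA", "AG", "GG"),
]


def synthetic_panel(n_markers: int = 7) -> MarkerPanel:
    """Generic panel: n−1 SNPs plus one categorical three-state marker, so
    both marker kinds are exercised."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    markers = [
        MarkerDef(f"snp{i + 1}", MarkerKind.SNP, _SNP_ALPHABETS[i % len(_SNP_ALPHABETS)])
        for i in range(n_markers - 1)
    ]
    markers.append(MarkerDef("cat1", MarkerKind.CATEGORICAL, ("No", "Single", "Double")))
    return MarkerPanel(tuple(markers))


@dataclass
class SimConfig:
    """Study-design knobs for one paired-cohort simulation.

    Defaults mirror the observed structure of the real data: a 7-marker
    panel, ~160 distinct GVs with power-law (exponent 1.5) frequencies,
    cohorts of about a thousand controls and 1500 cases, a small
    log-normal cross-cohort frequency perturbation, and no planted effects
    unless requested.
    """

    seed: int
    n_markers: int = 7
    n_gvs: int = 160
    powerlaw_exponent: float = 1.5
    planted_or: dict[int, float] = field(default_factory=dict)  # GV pool index -> OR
    planted_freq: dict[int, float] = field(default_factory=dict)  # pool index -> control freq
    cohort_sizes: tuple[tuple[int, int], tuple[int, int]] = ((1000, 1500), (1000, 1500))
    perturbation_scale: float = 0.05  # sd of log-normal tilt of cohort-B frequencies
    n_zero_sick: int = 0  # planted solely-sick GVs per cohort
    n_zero_healthy: int = 0
    zero_gv_size: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if any(v <= 0 for v in self.planted_or.values()):
            raise ValueError("planted ORs must be positive")
        if self.n_gvs < 1 + self.n_zero_sick + self.n_zero_healthy:
            raise ValueError("GV pool too small for the requested zero GVs")
        if not (0 <= max(self.planted_or, default=0) < self.n_gvs):
            raise ValueError("planted_or keys must index the GV pool")
        if not all(0 < f < 1 for f in self.planted_freq.values()):
            raise ValueError("planted control frequencies must lie in (0, 1)")
        if sum(self.planted_freq.values()) >= 1:
            raise ValueError("planted control frequencies must sum below 1")


def _gv_pool(rng: np.random.Generator, n_gvs: int, n_markers: int) -> list[GeneticVector]:
    pool: set[GeneticVector] = set()
    if n_gvs > 3**n_markers:
        raise ValueError(f"cannot draw {n_gvs} distinct GVs from 3^{n_markers} states")
    while len(pool) < n_gvs:
        pool.add(tuple(int(g) for g in rng.integers(1, 4, size=n_markers)))
    return sorted(pool)


def _labels_for(gv: GeneticVector, panel: MarkerPanel) -> tuple[str, ...]:
    return tuple(m.decode(g) for m, g in zip(panel, gv))


def generate_pair(
    config: SimConfig,
) -> tuple[CohortGenotypes, CohortGenotypes, dict]:
    """Draw paired cohorts A and B plus the generating truth record.

    The truth record carries the GV pool, per-cohort control frequencies,
    the planted per-GV odds ratios and the indices of planted zero GVs.
    """
    rng = np.random.default_rng(config.seed)
    panel = synthetic_panel(config.n_markers)
    pool = _gv_pool(rng, config.n_gvs, config.n_markers)

    n_zero = config.n_zero_sick + config.n_zero_healthy
    zero_sick = list(range(config.n_gvs - n_zero, config.n_gvs - config.n_zero_healthy))
    zero_healthy = list(range(config.n_gvs - config.n_zero_healthy, config.n_gvs))
    free = [i for i in range(config.n_gvs) if i not in zero_sick + zero_healthy]

    # heavy-tailed base frequencies over the non-zero pool, shuffled so
    # rank does not correlate with GV lexicographic order
    ranks = np.arange(1, len(free) + 1, dtype=float)
    base = ranks ** (-config.powerlaw_exponent)
    rng.shuffle(base)
    base /= base.sum()
    # pin requested control frequencies, scaling the rest into the remainder
    pinned = {free.index(i): f for i, f in config.planted_freq.items() if i in free}
    if pinned:
        rest = 1.0 - sum(pinned.values())
        unpinned = [j for j in range(len(free)) if j not in pinned]
        base[unpinned] *= rest / base[unpinned].sum()
        for j, f in pinned.items():
            base[j] = f

    truth = {
        "panel": panel,
        "pool": pool,
        "planted_or": dict(config.planted_or),
        "zero_sick": [pool[i] for i in zero_sick],
        "zero_healthy": [pool[i] for i in zero_healthy],
        "control_freqs": {},
        "case_freqs": {},
    }

    cohorts = []
    for c, (n_h, n_s) in enumerate(config.cohort_sizes):
        p_h = base.copy()
        if c == 1 and config.perturbation_scale > 0:
            p_h = p_h * np.exp(rng.normal(0.0, config.perturbation_scale, size=p_h.size))
            p_h /= p_h.sum()
        odds = np.array([config.planted_or.get(i, 1.0) for i in free])
        p_s = p_h * odds
        p_s /= p_s.sum()
        truth["control_freqs"][c] = dict(zip([pool[i] for i in free], p_h))
        truth["case_freqs"][c] = dict(zip([pool[i] for i in free], p_s))

        ctrl_counts = rng.multinomial(n_h, p_h)
        case_counts = rng.multinomial(n_s, p_s)

        ids: list[str] = []
        calls: list[tuple[str, ...]] = []
        pheno: list[Phenotype] = []

        def _emit(gv_idx: int, count: int, ph: Phenotype) -> None:
            labels = _labels_for(pool[gv_idx], panel)
            for _ in range(count):
                ids.append(f"C{c}_{'ctrl' if ph is Phenotype.CONTROL else 'case'}_{len(ids)}")
                calls.append(labels)
                pheno.append(ph)

        for j, i in enumerate(free):
            _emit(i, int(ctrl_counts[j]), Phenotype.CONTROL)
            _emit(i, int(case_counts[j]), Phenotype.CASE)
        for i in zero_sick:
            _emit(i, config.zero_gv_size, Phenotype.CASE)
        for i in zero_healthy:
            _emit(i, config.zero_gv_size, Phenotype.CONTROL)

        cohorts.append(CohortGenotypes(ids, calls, pheno))

    return cohorts[0], cohorts[1], truth


def write_fixture_tables(outdir: str | Path) -> dict[str, GVTable]:
    """Write the bundled published contrast GV tables and return them.

    Emits one TSV (+ JSON sidecar) per cohort and contrast class, in the
    standard GVTable dialect, so downstream tooling can be exercised
    against real published counts without raw data.
    """
    from gva.datasets import protective_contrast_tables, risk_contrast_tables

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, GVTable] = {}
    for kind, maker in (("risk", risk_contrast_tables), ("protective", protective_contrast_tables)):
        for cohort, table in maker().items():
            name = f"{kind}_{cohort.lower()}"
            table.to_tsv(outdir / f"{name}.tsv")
            tables[name] = table
    return tables
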