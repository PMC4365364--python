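"""Genetic vectors, GV group tables, index matrices and frequency maps.

A genetic vector (GV) is represented as a plain tuple of state indices
``γ ∈ {1, 2, 3}``, one per panel marker. Identical tuples hash equal, so
grouping a cohort by GV is a dictionary count. Each GV also has a unique
*index matrix*: the 3 × N binary matrix with a single 1 per column marking
which state each marker takes. Cohort-level genotype-frequency maps and the
contrast matrices of downstream modules are weighted averages of index
matrices, which is what makes the index-matrix representation useful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from gva.genotype_io import CohortGenotypes, MarkerPanel, Phenotype

__all__ = [
    "GeneticVector",
    "GVEntry",
    "GVTable",
    "encode_individual",
    "build_gv_table",
    "index_matrix",
    "frequency_map",
    "pair_rate",
    "crop",
    "common_basis",
]

GeneticVector = tuple[int, ...]

Group = Literal["h", "s"]


def encode_individual(labels: Sequence[str], panel: MarkerPanel) -> GeneticVector:
    """Encode one individual's complete raw labels into a GV tuple."""
    if len(labels) != len(panel):
        raise ValueError(f"expected {len(panel)} labels, got {len(labels)}")
    if any(lab is None for lab in labels):
        raise ValueError("incomplete genotype: individuals with missing calls have no GV")
    return tuple(m.encode(lab) for m, lab in zip(panel, labels))


def _check_gv(gv: GeneticVector, n_markers: int | None = None) -> None:
    if n_markers is not None and len(gv) != n_markers:
        raise ValueError(f"GV length {len(gv)} != panel length {n_markers}")
    if not gv or any(g not in (1, 2, 3) for g in gv):
        raise ValueError(f"invalid GV {gv!r}: states must be in {{1,2,3}}")


@dataclass
class GVEntry:
    """One GV group: ``n_h`` controls and ``n_s`` cases sharing the GV."""

    gv: GeneticVector
    n_h: int
    n_s: int

    def __post_init__(self) -> None:
        _check_gv(tuple(self.gv))
        self.gv = tuple(self.gv)
        if self.n_h < 0 or self.n_s < 0 or self.n_h + self.n_s < 1:
            raise ValueError(f"GV {self.gv}: counts ({self.n_h}, {self.n_s}) invalid")

    @property
    def n_t(self) -> int:
        return self.n_h + self.n_s


@dataclass
class GVTable:
    """Cohort summary: map GV → (n_h, n_s) plus cohort totals N_h, N_s.

    Totals default to the column sums over entries but may be set larger
    (e.g. raw cohort sizes when entries are a selected subset).
    """

    panel: MarkerPanel
    entries: dict[GeneticVector, GVEntry]
    N_h: int
    N_s: int

    def __post_init__(self) -> None:
        n = len(self.panel)
        for gv, e in self.entries.items():
            _check_gv(gv, n)
            if e.gv != gv:
                raise ValueError(f"entry key {gv} != entry.gv {e.gv}")
        if self.sum_h > self.N_h or self.sum_s > self.N_s:
            raise ValueError(
                f"entry sums ({self.sum_h}, {self.sum_s}) exceed totals ({self.N_h}, {self.N_s})"
            )

    @property
    def N_t(self) -> int:
        return self.N_h + self.N_s

    @property
    def sum_h(self) -> int:
        return sum(e.n_h for e in self.entries.values())

    @property
    def sum_s(self) -> int:
        return sum(e.n_s for e in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def gvs(self) -> list[GeneticVector]:
        """All GVs, in deterministic lexicographic order."""
        return sorted(self.entries)

    def sorted_entries(self) -> list[GVEntry]:
        return [self.entries[gv] for gv in self.gvs()]

    @classmethod
    def from_counts(
        cls,
        panel: MarkerPanel,
        rows: Iterable[tuple[Sequence[int], int, int]],
        N_h: int | None = None,
        N_s: int | None = None,
    ) -> "GVTable":
        """Build from pre-grouped ``(gv, n_h, n_s)`` rows (published summary
        tables are first-class inputs)."""
        entries: dict[GeneticVector, GVEntry] = {}
        for gv, n_h, n_s in rows:
            gv = tuple(gv)
            if gv in entries:
                raise ValueError(f"duplicate GV row {gv}")
            entries[gv] = GVEntry(gv, n_h, n_s)
        table = cls.__new__(cls)
        table.panel = panel
        table.entries = entries
        table.N_h = sum(e.n_h for e in entries.values()) if N_h is None else N_h
        table.N_s = sum(e.n_s for e in entries.values()) if N_s is None else N_s
        table.__post_init__()
        return table

    def restrict(self, gvs: Iterable[GeneticVector], retotal: bool = False) -> "GVTable":
        """Sub-table over ``gvs``; totals kept unless ``retotal`` is set."""
        sub = {gv: self.entries[gv] for gv in gvs}
        if retotal:
            return GVTable.from_counts(self.panel, [(e.gv, e.n_h, e.n_s) for e in sub.values()])
        return GVTable(self.panel, sub, self.N_h, self.N_s)

    # --- serialization: TSV body + JSON sidecar with panel and totals ---

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("gv_states\tn_h\tn_s\n")
            for e in self.sorted_entries():
                fh.write(f"{'-'.join(map(str, e.gv))}\t{e.n_h}\t{e.n_s}\n")
        sidecar = {
            "N_h": self.N_h,
            "N_s": self.N_s,
            "panel": [
                {"name": m.name, "kind": m.kind.value, "states": list(m.state_labels)}
                for m in self.panel
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GVTable":
        from gva.genotype_io import MarkerDef, MarkerKind

        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        panel = MarkerPanel(
            tuple(
                MarkerDef(m["name"], MarkerKind(m["kind"]), tuple(m["states"]))
                for m in sidecar["panel"]
            )
        )
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["gv_states", "n_h", "n_s"]:
                raise ValueError(f"{path}: unexpected header {header}")
            for line in fh:
                if not line.strip():
                    continue
                states, n_h, n_s = line.rstrip("\n").split("\t")
                rows.append((tuple(int(x) for x in states.split("-")), int(n_h), int(n_s)))
        return cls.from_counts(panel, rows, N_h=sidecar["N_h"], N_s=sidecar["N_s"])


def build_gv_table(cohort: CohortGenotypes, panel: MarkerPanel) -> GVTable:
    """Group a cohort's complete individuals by GV and count phenotypes."""
    complete = cohort.complete()
    if len(complete) == 0:
        raise ValueError("no individuals with complete genotypes")
    counts: dict[GeneticVector, list[int]] = {}
    for labels, ph in zip(complete.calls, complete.phenotype):
        gv = encode_individual(labels, panel)
        pair = counts.setdefault(gv, [0, 0])
        pair[1 if ph is Phenotype.CASE else 0] += 1
    return GVTable.from_counts(panel, [(gv, c[0], c[1]) for gv, c in counts.items()])


def index_matrix(gv: GeneticVector) -> np.ndarray:
    """The 3 × N binary matrix with values[γ-1, i] = 1 iff marker i is in state γ."""
    _check_gv(tuple(gv))
    m = np.zeros((3, len(gv)), dtype=np.int64)
    for i, gamma in enumerate(gv):
        m[gamma - 1, i] = 1
    return m


def _group_counts(table: GVTable, group: Group) -> tuple[np.ndarray, list[GeneticVector]]:
    gvs = table.gvs()
    counts = np.array(
        [table.entries[gv].n_h if group == "h" else table.entries[gv].n_s for gv in gvs],
        dtype=float,
    )
    return counts, gvs

def frequency_map(table: GVTable, group: Group) -> np.ndarray:
    """Genotype-frequency map: per-marker state fractions in one phenotype group.

    Equals the average of the per-GV index matrices weighted by the group
    counts n_ν divided by the group total; every column sums to 1.
    """
    if group not in ("h", "s"):
        raise ValueError(f"group must be 'h' or 's', got {group!r}")
    counts, gvs = _group_counts(table, group)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} is empty")
    m = np.zeros((3, len(table.panel)))
    for w, gv in zip(counts, gvs):
        if w:
            m += w * index_matrix(gv)
    return m / total


def pair_rate(
    table: GVTable,
    a: tuple[int, int],
    b: tuple[int, int],
    group: Group,
) -> float:
    """Fraction of group individuals in state γ at marker i AND γ′ at marker i′.

    ``a`` and ``b`` are (marker position, state) pairs; with a == b this
    reduces to the corresponding frequency-map entry.
    """
    (i, gamma), (i2, gamma2) = a, b
    n = len(table.panel)
    for pos, g in ((i, gamma), (i2, gamma2)):
        if not (0 <= pos < n):
            raise ValueError(f"marker position {pos} outside panel of length {n}")
        if g not in (1, 2, 3):
            raise ValueError(f"state {g} not in {{1,2,3}}")
    if i == i2 and gamma != gamma2:
        return 0.0
    counts, gvs = _group_counts(table, group)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"group {group!r} is empty")
    hit = sum(
        w for w, gv in zip(counts, gvs) if gv[i] == gamma and gv[i2] == gamma2
    )
    return float(hit / total)


def crop(table: GVTable, keep: Sequence[int]) -> GVTable:
    """Project GVs onto marker positions ``keep``, merging identical projections.

    Merging sums the group counts, so cohort totals are conserved. Used to
    ask which markers drive an association: markers whose removal leaves
    the contrast intact are not doing the work.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must name at least one marker position")
    n = len(table.panel)
    if len(set(keep)) != len(keep) or any(not (0 <= k < n) for k in keep):
        raise ValueError(f"invalid marker positions {keep} for panel of length {n}")
    sub_panel = MarkerPanel(tuple(table.panel.markers[k] for k in keep))
    merged: dict[GeneticVector, list[int]] = {}
    for gv, e in table.entries.items():
        short = tuple(gv[k] for k in keep)
        pair = merged.setdefault(short, [0, 0])
        pair[0] += e.n_h
        pair[1] += e.n_s
    return GVTable.from_counts(
        sub_panel,
        [(gv, c[0], c[1]) for gv, c in merged.items()],
        N_h=table.N_h,
        N_s=table.N_s,
    )


def common_basis(
    tables: Sequence[GVTable],
) -> tuple[list[GeneticVector], list[np.ndarray]]:
    """Union of the tables' GV sets plus per-table membership masks.

    The union, in lexicographic order, is the complete basis in which all
    cohorts can be expressed; mask[t][j] is True when basis GV j occurs in
    table t. GVs present in every table are the *common* GVs.
    """
    if not tables:
        raise ValueError("need at least one table")
    names0 = tables[0].panel.names
    for t in tables[1:]:
        if t.panel.names != names0:
            raise ValueError(f"panels differ: {names0} vs {t.panel.names}")
    basis = sorted(set().union(*(set(t.entries) for t in tables)))
    masks = [np.array([gv in t.entries for gv in basis], dtype=bool) for t in tables]
    return basis, masks
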