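"""Genotype and phenotype input/output and three-state encoding.

Every marker in a panel — whether a biallelic SNP or a categorical variable
such as the HLA-DRB1 shared-epitope (SE) copy number — takes exactly one of
three ordered states, indexed ``γ ∈ {1, 2, 3}``. For a SNP the states are
the homozygous-reference, heterozygous and homozygous-alternate genotypes;
for SE they are No / Single / Double copies. The state *order* is part of
the panel definition and must be identical across cohorts being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "MarkerKind",
    "MarkerDef",
    "MarkerPanel",
    "Phenotype",
    "CohortGenotypes",
    "encode_genotype",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotypes",
    "read_vcf",
]


class MarkerKind(str, Enum):
    SNP = "snp"
    CATEGORICAL = "categorical"


class Phenotype(int, Enum):
    CONTROL = 0
    CASE = 1


def _normalize_label(kind: MarkerKind, label: str) -> str:
    # Heterozygote order is arbitrary in genotype calls: "CA" and "AC" are
    # the same state, so SNP labels are canonicalized by sorting alleles.
    if kind is MarkerKind.SNP and len(label) == 2:
        return "".join(sorted(label))
    return label


@dataclass(frozen=True)
class MarkerDef:
    """One marker: its name and the ordered triple of state labels."""

    name: str
    kind: MarkerKind
    state_labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        kind = MarkerKind(self.kind)
        object.__setattr__(self, "kind", kind)
        labels = tuple(self.state_labels)
        if len(labels) != 3:
            raise ValueError(
                f"marker {self.name!r}: need exactly 3 state labels, got {labels!r}"
            )
        normalized = tuple(_normalize_label(kind, s) for s in labels)
        if len(set(normalized)) != 3:
            raise ValueError(f"marker {self.name!r}: state labels not distinct: {labels!r}")
        object.__setattr__(self, "state_labels", labels)

    def encode(self, label: str) -> int:
        """Map a raw state label to its 1-based state index γ."""
        want = _normalize_label(self.kind, label)
        for gamma, known in enumerate(self.state_labels, start=1):
            if _normalize_label(self.kind, known) == want:
                return gamma
        raise ValueError(
            f"marker {self.name!r}: unknown state label {label!r} "
            f"(expected one of {self.state_labels})"
        )

    def decode(self, gamma: int) -> str:
        if gamma not in (1, 2, 3):
            raise ValueError(f"state index must be 1, 2 or 3, got {gamma}")
        return self.state_labels[gamma - 1]


def encode_genotype(marker: MarkerDef, label: str) -> int:
    """1-based position of ``label`` in the marker's state alphabet."""
    return marker.encode(label)


@dataclass(frozen=True)
class MarkerPanel:
    """Fixed, ordered collection of markers defining the GV coordinate system.

    The order is chosen once and must be identical for every cohort entering
    a comparison: two GVs are only comparable coordinate by coordinate.
    """

    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        if not markers:
            raise ValueError("panel must contain at least one marker")
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker names in panel: {names}")
        object.__setattr__(self, "markers", markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in panel {self.names}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        """Load a panel from a YAML/JSON list of {name, kind, states} entries."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw, dict):
            raw = raw.get("markers", raw)
        markers = [
            MarkerDef(m["name"], MarkerKind(m.get("kind", "snp")), tuple(m["states"]))
            for m in raw
        ]
        return cls(tuple(markers))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "markers": [
                {"name": m.name, "kind": m.kind.value, "states": list(m.state_labels)}
                for m in self.markers
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class CohortGenotypes:
    """Per-individual raw genotype labels plus case/control phenotype.

    ``calls[i][j]`` is the raw label of individual *i* at panel marker *j*,
    or ``None`` for a missing call. Individuals with any missing or
    unrecognized label are *flagged*, never silently dropped: a GV is
    defined only for a complete set of calls, so flagged individuals are
    excluded from GV construction and reported.
    """

    individual_ids: list[str]
    calls: list[tuple[Optional[str], ...]]
    phenotype: list[Phenotype]
    flagged: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        if not (len(self.calls) == len(self.phenotype) == n):
            raise ValueError("individual_ids, calls and phenotype lengths differ")
        widths = {len(c) for c in self.calls}
        if len(widths) > 1:
            raise ValueError(f"inconsistent call widths: {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.individual_ids)

    @property
    def n_controls(self) -> int:
        return sum(1 for p in self.phenotype if p is Phenotype.CONTROL)

    @property
    def n_cases(self) -> int:
        return sum(1 for p in self.phenotype if p is Phenotype.CASE)

    def complete(self) -> "CohortGenotypes":
        """Sub-cohort of individuals with complete, recognized genotypes."""
        keep = [i for i in range(len(self)) if i not in self.flagged]
        return CohortGenotypes(
            [self.individual_ids[i] for i in keep],
            [self.calls[i] for i in keep],
            [self.phenotype[i] for i in keep],
        )


def _parse_pheno(code: str, where: str) -> Phenotype:
    if code == "0":
        return Phenotype.CONTROL
    if code == "1":
        return Phenotype.CASE
    raise ValueError(f"{where}: unknown phenotype code {code!r} (expected 0 or 1)")


def read_genotype_table(path: str | Path, panel: MarkerPanel) -> CohortGenotypes:
    """Read the tab-delimited dialect ``id<TAB>pheno<TAB><marker1>...``.

    Marker columns are located by the header names, so column order in the
    file need not match the panel. Rows with an ``NA`` or a label outside
    the marker's alphabet are retained but flagged.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, expected a header line")
        header = header_line.rstrip("\n").split("\t")
        if header[:2] != ["id", "pheno"]:
            raise ValueError(f"{path}: header must start with 'id<TAB>pheno', got {header[:2]}")
        col_of = {}
        for m in panel:
            if m.name not in header:
                raise ValueError(f"{path}: missing column for panel marker {m.name!r}")
            col_of[m.name] = header.index(m.name)

        ids: list[str] = []
        calls: list[tuple[Optional[str], ...]] = []
        pheno: list[Phenotype] = []
        flagged: set[int] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            ids.append(fields[0])
            pheno.append(_parse_pheno(fields[1], f"{path}:{lineno}"))
            row: list[Optional[str]] = []
            ok = True
            for m in panel:
                label = fields[col_of[m.name]]
                if label == "NA":
                    row.append(None)
                    ok = False
                    continue
                try:
                    m.encode(label)
                except ValueError:
                    ok = False
                row.append(label)
            calls.append(tuple(row))
            if not ok:
                flagged.add(len(ids) - 1)
    return CohortGenotypes(ids, calls, pheno, flagged)


def write_genotype_table(cohort: CohortGenotypes, panel: MarkerPanel, path: str | Path) -> None:
    """Write ``cohort`` in the tabular dialect read by :func:`read_genotype_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "pheno", *panel.names]) + "\n")
        for ind, row, ph in zip(cohort.individual_ids, cohort.calls, cohort.phenotype):
            labels = ["NA" if v is None else v for v in row]
            fh.write("\t".join([ind, str(ph.value), *labels]) + "\n")


def read_phenotypes(path: str | Path) -> dict[str, Phenotype]:
    """Read the two-column ``id<TAB>pheno`` file (0 = control, 1 = case)."""
    out: dict[str, Phenotype] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "id" and lineno == 1:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>pheno'")
            out[fields[0]] = _parse_pheno(fields[1], f"{path}:{lineno}")
    return out


def read_vcf(path: str | Path, panel: MarkerPanel, pheno_path: str | Path) -> CohortGenotypes:
    """Read panel SNP genotypes from a VCF plus a phenotype sidecar file.

    Panel markers are matched by VCF ID. Diploid GT fields map onto state
    indices as 0/0 → 1, 0/1 or 1/0 → 2, 1/1 → 3; phasing separators are
    ignored because the analysis is genotype-based, not haplotype-based.
    Missing GTs flag the individual. Categorical (non-SNP) markers cannot
    come from a VCF.
    """
    import pysam

    phenos = read_phenotypes(pheno_path)
    for m in panel:
        if m.kind is not MarkerKind.SNP:
            raise ValueError(
                f"marker {m.name!r} is categorical; VCF input supports SNP-only panels"
            )

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        records: dict[str, object] = {}
        wanted = set(panel.names)
        for rec in vf:
            if rec.id in wanted:
                if rec.id in records:
                    raise ValueError(f"duplicate VCF record for marker {rec.id!r}")
                records[rec.id] = rec

        missing = [n for n in panel.names if n not in records]
        if missing:
            raise ValueError(f"panel markers absent from VCF: {missing}")

        unphenotyped = [s for s in samples if s not in phenos]
        if unphenotyped:
            raise ValueError(f"samples without phenotype: {unphenotyped}")

        gt_per_marker: dict[str, list[Optional[int]]] = {}
        for m in panel:
            rec = records[m.name]
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"marker {m.name!r}: multiallelic records are not supported")
            states: list[Optional[int]] = []
            for s in samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    states.append(None)
                    continue
                if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
                    raise ValueError(f"marker {m.name!r}, sample {s}: unsupported GT {alleles}")
                states.append(1 + sum(alleles))  # 0/0→1, 0/1→2, 1/1→3
            gt_per_marker[m.name] = states

    ids: list[str] = []
    calls: list[tuple[Optional[str], ...]] = []
    pheno: list[Phenotype] = []
    flagged: set[int] = set()
    for j, s in enumerate(samples):
        ids.append(s)
        pheno.append(phenos[s])
        row: list[Optional[str]] = []
        for m in panel:
            gamma = gt_per_marker[m.name][j]
            row.append(None if gamma is None else m.decode(gamma))
        calls.append(tuple(row))
        if any(v is None for v in row):
            flagged.add(j)
    return CohortGenotypes(ids, calls, pheno, flagged)
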