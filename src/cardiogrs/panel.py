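"""SNP panel data model for CHD genetic risk scores.

A *panel* is an ordered set of SNPs, each carrying a risk allele, a
published per-allele odds ratio from white GWAS/meta-analyses, and a
log-odds weight used by the weighted score.  The bundled ``grs19`` panel
is the 19-SNP CHD panel; 14 of its SNPs form the ``GRS14`` subset
(membership is an explicit flag on each SNP).  Per-population risk-allele
frequency (RAF) tables for Afro-Caribbean and white (NPHSII) controls are
bundled alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "SnpDefinition",
    "SnpPanel",
    "PanelError",
    "load_panel",
    "write_panel",
    "grs14_subset",
    "load_raf_table",
    "BUNDLED_PANELS",
    "BUNDLED_RAF_TABLES",
]

BUNDLED_PANELS = ("grs19",)
BUNDLED_RAF_TABLES = ("afro_caribbean_controls", "white_controls")

_REQUIRED_COLUMNS = (
    "rsid",
    "chromosome",
    "locus",
    "risk_allele",
    "reference_allele",
    "published_or",
)

# Five low-effect SNPs excluded from the 14-SNP score on the bundled panel.
GRS14_EXCLUDED = frozenset(
    {"rs4341", "rs1042031", "rs708272", "rs1799983", "rs17228212"}
)


class PanelError(ValueError):
    """Raised when a panel file is malformed or internally inconsistent."""


@dataclass(frozen=True)
class SnpDefinition:
    """One SNP of a risk-score panel.

    ``weight`` is the log-odds coefficient used by the weighted score and
    defaults to ``ln(published_or)`` when the source file carries no
    explicit weight column.
    """

    rsid: str
    chromosome: str
    locus: str
    risk_allele: str
    reference_allele: str
    published_or: float
    weight: float | None = None
    in_grs14: bool = True

    def __post_init__(self) -> None:
        if self.published_or <= 0:
            raise PanelError(
                f"{self.rsid}: published OR must be > 0, got {self.published_or}"
            )
        if self.risk_allele == self.reference_allele:
            raise PanelError(
                f"{self.rsid}: risk and reference allele are both "
                f"{self.risk_allele!r}"
            )
        if self.weight is None:
            object.__setattr__(self, "weight", math.log(self.published_or))


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, rsid-unique collection of :class:`SnpDefinition`."""

    snps: tuple[SnpDefinition, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelError(f"duplicate rsid(s) in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpDefinition]:
        return iter(self.snps)

    def __getitem__(self, rsid: str) -> SnpDefinition:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def weights(self) -> Mapping[str, float]:
        return {s.rsid: float(s.weight) for s in self.snps}

    @property
    def risk_alleles(self) -> Mapping[str, str]:
        return {s.rsid: s.risk_allele for s in self.snps}

    def with_weights(self, weights: Mapping[str, float]) -> "SnpPanel":
        """Return a copy with per-SNP weights overridden (e.g. external βs)."""
        unknown = set(weights) - set(self.rsids)
        if unknown:
            raise PanelError(f"weights supplied for SNPs not in panel: {sorted(unknown)}")
        snps = tuple(
            replace(s, weight=float(weights.get(s.rsid, s.weight))) for s in self.snps
        )
        return SnpPanel(snps, name=self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "chromosome": [s.chromosome for s in self.snps],
                "locus": [s.locus for s in self.snps],
                "risk_allele": [s.risk_allele for s in self.snps],
                "reference_allele": [s.reference_allele for s in self.snps],
                "published_or": [s.published_or for s in self.snps],
                "weight": [s.weight for s in self.snps],
                "in_grs14": [int(s.in_grs14) for s in self.snps],
            }
        )


def _bundled(name: str) -> Path:
    return Path(str(resources.files("cardiogrs.data").joinpath(f"{name}.tsv")))


def load_panel(source: str | Path = "grs19") -> SnpPanel:
    """Load a panel from a TSV file or a bundled fixture name.

    The file must carry columns rsid, chromosome, locus, risk_allele,
    reference_allele, published_or; optional columns weight (log-odds,
    defaults to ln published_or) and in_grs14 (0/1, defaults to 1).
    """
    if isinstance(source, str) and source in BUNDLED_PANELS:
        path, name = _bundled(source), source
    else:
        path = Path(source)
        name = path.stem
        if not path.exists():
            raise PanelError(f"panel file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str}, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required column(s) {missing}")
    snps = []
    for i, row in df.iterrows():
        if row["published_or"] <= 0:
            raise PanelError(
                f"{path} row {i} ({row['rsid']}): non-positive OR {row['published_or']}"
            )
        weight = None
        if "weight" in df.columns and pd.notna(row["weight"]):
            weight = float(row["weight"])
        snps.append(
            SnpDefinition(
                rsid=row["rsid"],
                chromosome=str(row["chromosome"]),
                locus=str(row["locus"]),
                risk_allele=str(row["risk_allele"]),
                reference_allele=str(row["reference_allele"]),
                published_or=float(row["published_or"]),
                weight=weight,
                in_grs14=bool(int(row["in_grs14"])) if "in_grs14" in df.columns else True,
            )
        )
    try:
        return SnpPanel(tuple(snps), name=name)
    except PanelError as exc:
        raise PanelError(f"{path}: {exc}") from exc


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel as TSV; ``load_panel`` round-trips it bit-identically."""
    df = panel.to_frame()
    # shortest-round-trip repr so reload is bit-identical
    for col in ("published_or", "weight"):
        df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False)


def grs14_subset(panel: SnpPanel) -> SnpPanel:
    """Restrict a panel to its flagged 14-SNP subset.

    On the bundled 19-SNP panel the subset drops the five lowest-effect
    SNPs (published OR <= 1.04) and must contain exactly 14 entries.
    """
    kept = tuple(s for s in panel.snps if s.in_grs14)
    if panel.name == "grs19" and len(kept) != 14:
        raise PanelError(
            f"grs19 fixture inconsistency: GRS14 subset has {len(kept)} SNPs, expected 14"
        )
    if not kept:
        raise PanelError("panel has no SNPs flagged in_grs14")
    return SnpPanel(kept, name=f"{panel.name}:grs14" if panel.name != "grs19" else "grs14")


def load_raf_table(source: str | Path) -> pd.DataFrame:
    """Load a per-population risk-allele-frequency table.

    Bundled names: ``afro_caribbean_controls`` (n=359) and
    ``white_controls`` (n=1214, NPHSII men).  Returns a DataFrame indexed
    by rsid with columns ``raf`` and ``n_individuals``.
    """
    if isinstance(source, str) and source in BUNDLED_RAF_TABLES:
        path = _bundled(source)
    else:
        path = Path(source)
        if not path.exists():
            raise PanelError(f"RAF table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str}).set_index("rsid")
    bad = df[(df["raf"] < 0) | (df["raf"] > 1)]
    if len(bad):
        raise PanelError(f"{path}: RAF outside [0,1] for {list(bad.index)}")
    return df
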