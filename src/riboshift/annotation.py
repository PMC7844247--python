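"""Protein annotation catalog: ribosomal-protein classes, families, paralogs, markers.

Every protein identifier entering the compositional analysis is resolved
against a catalog that assigns it to one of the ribosomal-protein (RP)
classes — cytosolic 40S/60S RPs, organellar (plastid/mitochondrial) 30S/50S
RPs, ribosome biogenesis factors, eIF3 subunits — or to ``other``.  Two
biogenesis factors, eIF6A (AT3G55620) and NMD3 (AT2G03820), act as pre-60S
markers: their abundance maxima identify the non-translating 60S fractions
of a sucrose gradient.

A small default catalog covering the proteins discussed in the compositional
analysis ships with the package; complete catalogs for real data are supplied
by the user as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

RP_CLASSES = ("RP40S", "RP60S", "RP30S_org", "RP50S_org", "biogenesis", "eIF3", "other")
MARKER_ROLES = ("pre60S_marker", "preinit_marker", "none")

REQUIRED_COLUMNS = (
    "protein_id",
    "gene_model",
    "rp_class",
    "family",
    "paralog",
    "marker_role",
    "paralog_specific",
)


@dataclass(frozen=True)
class ProteinAnnotation:
    """One catalog entry.

    ``paralog_specific`` records whether the peptide evidence behind the
    identifier distinguishes the paralog from its family members; shared
    peptide groups are carried as single entries with this flag False and
    reported as family-level calls downstream.
    """

    protein_id: str
    gene_model: str
    rp_class: str
    family: str = ""
    paralog: str = ""
    marker_role: str = "none"
    paralog_specific: bool = True

    def __post_init__(self) -> None:
        if self.rp_class not in RP_CLASSES:
            raise ValueError(f"unknown rp_class {self.rp_class!r} for {self.protein_id}")
        if self.marker_role not in MARKER_ROLES:
            raise ValueError(f"unknown marker_role {self.marker_role!r} for {self.protein_id}")


@dataclass
class AnnotationCatalog:
    """Catalog of :class:`ProteinAnnotation`, indexed by protein and gene model."""

    entries: list[ProteinAnnotation]
    _by_protein: dict[str, ProteinAnnotation] = field(init=False, repr=False)
    _by_gene: dict[str, list[ProteinAnnotation]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_protein = {}
        self._by_gene = {}
        for e in self.entries:
            if e.protein_id in self._by_protein:
                raise ValueError(f"duplicate protein_id {e.protein_id!r} in catalog")
            self._by_protein[e.protein_id] = e
            self._by_gene.setdefault(e.gene_model, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def get(self, protein_id: str) -> ProteinAnnotation | None:
        return self._by_protein.get(protein_id)

    def by_gene_model(self, gene_model: str) -> list[ProteinAnnotation]:
        return list(self._by_gene.get(gene_model, []))

    def ids_of_class(self, rp_class: str) -> list[str]:
        return [e.protein_id for e in self.entries if e.rp_class == rp_class]

    def markers(self, role: str = "pre60S_marker") -> list[ProteinAnnotation]:
        return [e for e in self.entries if e.marker_role == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "gene_model": e.gene_model,
                    "rp_class": e.rp_class,
                    "family": e.family,
                    "paralog": e.paralog,
                    "marker_role": e.marker_role,
                    "paralog_specific": e.paralog_specific,
                }
                for e in self.entries
            ],
            columns=list(REQUIRED_COLUMNS),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def catalog_from_frame(df: pd.DataFrame) -> AnnotationCatalog:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError("annotation table is empty")
    entries = [
        ProteinAnnotation(
            protein_id=str(r.protein_id),
            gene_model=str(r.gene_model),
            rp_class=str(r.rp_class),
            family="" if pd.isna(r.family) else str(r.family),
            paralog="" if pd.isna(r.paralog) else str(r.paralog),
            marker_role="none" if pd.isna(r.marker_role) or r.marker_role == "" else str(r.marker_role),
            paralog_specific=bool(r.paralog_specific) if not pd.isna(r.paralog_specific) else True,
        )
        for r in df.itertuples()
    ]
    return AnnotationCatalog(entries)


def load_annotation(path: str | Path) -> AnnotationCatalog:
    """Load an annotation TSV into a catalog.

    Raises ``ValueError`` naming the column when a required column is
    missing, on duplicate ``protein_id``, and on an empty file.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"annotation file {path} is empty") from exc
    if "paralog_specific" in df.columns:
        df["paralog_specific"] = df["paralog_specific"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )
    return catalog_from_frame(df)


def classify(catalog: AnnotationCatalog, protein_id: str) -> str:
    """Return the RP class of ``protein_id``; unknown identifiers are ``other``."""
    entry = catalog.get(protein_id)
    if entry is None:
        logger.warning("protein %s not in catalog; classified as 'other'", protein_id)
        return "other"
    return entry.rp_class


def default_catalog() -> AnnotationCatalog:
    """The packaged catalog of proteins discussed in the compositional analysis.

    Covers the pre-60S markers, the named cytosolic 60S/40S RP paralogs and
    the eIF3 subunits; it is illustrative, not a complete Arabidopsis RP
    catalog.
    """
    with resources.files("riboshift.data").joinpath("default_catalog.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df["paralog_specific"] = df["paralog_specific"].map(lambda v: str(v).lower() == "true")
    return catalog_from_frame(df)


def make_catalog(rows: Iterable[dict]) -> AnnotationCatalog:
    """Build a catalog from plain dicts (convenience for simulations/tests)."""
    return AnnotationCatalog([ProteinAnnotation(**row) for row in rows])
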