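"""Gene catalog: per-gene records for a CYP (cytochrome P450) complement.

A catalog row records the CYP nomenclature name, family/subfamily/clan
membership, functional status, B/D type (biosynthesis vs detoxification),
genomic cluster membership, and — for pseudogenes — the originating
functional gene, when identified.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

CYP_TYPES = {"B", "D", "unknown"}
STATUSES = {"functional", "pseudogene"}

REQUIRED_COLUMNS = [
    "name", "species", "family", "subfamily", "clan",
    "cyp_type", "status", "cluster", "parent_gene",
]


class CatalogFormatError(ValueError):
    """Raised for structurally invalid catalog files."""


class CatalogValidationError(ValueError):
    """Raised when catalog contents violate an invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene in one species."""

    name: str
    species: str
    family: str
    subfamily: str
    cyp_type: str = "unknown"
    status: str = "functional"
    clan: Optional[str] = None
    cluster: Optional[str] = None
    parent_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cyp_type not in CYP_TYPES:
            raise CatalogValidationError(
                f"{self.name}: cyp_type {self.cyp_type!r} not in {sorted(CYP_TYPES)}"
            )
        if self.status not in STATUSES:
            raise CatalogValidationError(
                f"{self.name}: status {self.status!r} not in {sorted(STATUSES)}"
            )
        if not self.subfamily.startswith(self.family):
            raise CatalogValidationError(
                f"{self.name}: subfamily {self.subfamily!r} does not extend "
                f"family {self.family!r}"
            )
        if self.parent_gene is not None and self.status != "pseudogene":
            raise CatalogValidationError(
                f"{self.name}: parent_gene set on a functional gene"
            )


@dataclass
class GeneCatalog:
    """Collection of :class:`GeneRecord` with uniqueness over (species, name)."""

    records: list[GeneRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.species, r.name)
            if key in seen:
                raise CatalogValidationError(f"duplicate gene {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def count(self, **filters) -> int:
        """Number of records matching all field predicates.

        A filter value may be a plain value (equality), a callable predicate,
        or the sentinel string ``"*"`` meaning "field is present (not None)".
        """
        return len(self.select(**filters))

    def select(self, **filters) -> list[GeneRecord]:
        fields = {f.name for f in GeneRecord.__dataclass_fields__.values()} \
            if hasattr(GeneRecord, "__dataclass_fields__") else set()
        out = []
        for r in self.records:
            ok = True
            for key, want in filters.items():
                if key not in GeneRecord.__dataclass_fields__:
                    raise CatalogValidationError(f"unknown field {key!r}")
                got = getattr(r, key)
                if callable(want):
                    ok = want(got)
                elif want == "*":
                    ok = got is not None
                else:
                    ok = got == want
                if not ok:
                    break
            if ok:
                out.append(r)
        return out


def _clean(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a TSV gene catalog (``#`` lines are comments)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise CatalogFormatError(f"{path}: empty catalog file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(GeneRecord(
            name=_clean(row["name"]) or "",
            species=_clean(row["species"]) or "",
            family=_clean(row["family"]) or "",
            subfamily=_clean(row["subfamily"]) or "",
            cyp_type=_clean(row["cyp_type"]) or "unknown",
            status=_clean(row["status"]) or "functional",
            clan=_clean(row["clan"]),
            cluster=_clean(row["cluster"]),
            parent_gene=_clean(row["parent_gene"]),
        ))
    return GeneCatalog(records=records, provenance=str(path))


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    rows = []
    for r in catalog.records:
        rows.append({
            "name": r.name, "species": r.species, "family": r.family,
            "subfamily": r.subfamily, "clan": r.clan or "",
            "cyp_type": r.cyp_type, "status": r.status,
            "cluster": r.cluster or "", "parent_gene": r.parent_gene or "",
        })
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def load_human_catalog() -> GeneCatalog:
    """The packaged human CYP catalog (57 functional genes, 19 pseudogenes)."""
    ref = importlib.resources.files("cypevol.data") / "human_cyp_catalog.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_catalog(p)
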