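"""Ligand-receptor interaction database: schema, loading, validation, queries.

An interaction couples a (possibly multimeric) ligand with a (possibly
multimeric) receptor complex and may carry four classes of modulating
cofactors: soluble agonists and antagonists, and membrane-bound
co-stimulatory and co-inhibitory receptors.  A receptor or ligand complex
is inactive if any of its subunits is unexpressed, so the subunit lists
are hard requirements, while cofactor sets are optional modulators.
Interactions are grouped into signaling pathways (exactly one pathway per
interaction) and carry one of three annotation classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ANNOTATION_CLASSES = ("secreted_signaling", "ecm_receptor", "cell_cell_contact")

TSV_COLUMNS = [
    "id",
    "ligand_subunits",
    "receptor_subunits",
    "agonists",
    "antagonists",
    "co_stimulatory",
    "co_inhibitory",
    "pathway",
    "annotation",
    "evidence",
]

#: separator for multi-gene fields inside one TSV cell
FIELD_SEP = ","


class DatabaseError(ValueError):
    """Schema or validation failure in a ligand-receptor database."""


def _check_gene(name: str, where: str) -> str:
    if not isinstance(name, str) or not name or any(c.isspace() for c in name):
        raise DatabaseError(f"{where}: invalid gene symbol {name!r}")
    return name


@dataclass
class LRInteraction:
    """One ligand-receptor rule with cofactors and pathway membership."""

    id: str
    ligand_subunits: list[str]
    receptor_subunits: list[str]
    agonists: frozenset[str] = frozenset()
    antagonists: frozenset[str] = frozenset()
    co_stimulatory: frozenset[str] = frozenset()
    co_inhibitory: frozenset[str] = frozenset()
    pathway: str = ""
    annotation: str = "secreted_signaling"
    evidence: str = ""

    def __post_init__(self):
        where = f"interaction {self.id!r}"
        if not self.id:
            raise DatabaseError("interaction id must be non-empty")
        if len(self.ligand_subunits) < 1:
            raise DatabaseError(f"{where}: empty ligand subunit list")
        if len(self.receptor_subunits) < 1:
            raise DatabaseError(f"{where}: empty receptor subunit list")
        for lst, nm in ((self.ligand_subunits, "ligand"), (self.receptor_subunits, "receptor")):
            if len(set(lst)) != len(lst):
                raise DatabaseError(f"{where}: duplicate {nm} subunits")
            for g in lst:
                _check_gene(g, where)
        for s in (self.agonists, self.antagonists, self.co_stimulatory, self.co_inhibitory):
            for g in s:
                _check_gene(g, where)
        if not self.pathway:
            raise DatabaseError(f"{where}: pathway must be non-empty")
        if self.annotation not in ANNOTATION_CLASSES:
            raise DatabaseError(
                f"{where}: annotation {self.annotation!r} not one of {ANNOTATION_CLASSES}"
            )

    @property
    def ligand_name(self) -> str:
        """Display name, derived from subunits (single source of truth)."""
        return "_".join(self.ligand_subunits)

    @property
    def receptor_name(self) -> str:
        return "_".join(self.receptor_subunits)

    @property
    def is_heteromeric(self) -> bool:
        return len(self.ligand_subunits) > 1 or len(self.receptor_subunits) > 1

    def genes(self) -> set[str]:
        return (
            set(self.ligand_subunits)
            | set(self.receptor_subunits)
            | set(self.agonists)
            | set(self.antagonists)
            | set(self.co_stimulatory)
            | set(self.co_inhibitory)
        )


@dataclass
class LRDatabase:
    """A validated collection of ligand-receptor interactions.

    ``pathways`` and ``gene_universe`` are derived on construction and kept
    consistent with ``interactions``.
    """

    interactions: list[LRInteraction]
    pathways: dict[str, list[str]] = field(init=False)
    gene_universe: set[str] = field(init=False)

    def __post_init__(self):
        if not self.interactions:
            raise DatabaseError("no interactions")
        ids = [it.id for it in self.interactions]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise DatabaseError(f"duplicate interaction ids: {dupes}")
        self.pathways = {}
        self.gene_universe = set()
        for it in self.interactions:
            self.pathways.setdefault(it.pathway, []).append(it.id)
            self.gene_universe |= it.genes()

    def __len__(self) -> int:
        return len(self.interactions)

    def __getitem__(self, interaction_id: str) -> LRInteraction:
        for it in self.interactions:
            if it.id == interaction_id:
                return it
        raise KeyError(interaction_id)

    def pathway_of(self, interaction_id: str) -> str:
        return self[interaction_id].pathway


def _split_field(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [g.strip() for g in str(cell).split(FIELD_SEP) if g.strip()]


def _row_to_interaction(row: dict, where: str) -> LRInteraction:
    try:
        return LRInteraction(
            id=str(row["id"]),
            ligand_subunits=_split_field(row["ligand_subunits"]),
            receptor_subunits=_split_field(row["receptor_subunits"]),
            agonists=frozenset(_split_field(row.get("agonists"))),
            antagonists=frozenset(_split_field(row.get("antagonists"))),
            co_stimulatory=frozenset(_split_field(row.get("co_stimulatory"))),
            co_inhibitory=frozenset(_split_field(row.get("co_inhibitory"))),
            pathway=str(row.get("pathway") or ""),
            annotation=str(row.get("annotation") or ""),
            evidence="" if pd.isna(row.get("evidence")) else str(row.get("evidence")),
        )
    except DatabaseError as e:
        raise DatabaseError(f"{where}: {e}") from None


def load_database(path, dialect: str = "tsv") -> LRDatabase:
    """Load and validate a ligand-receptor database from TSV or JSON.

    The TSV dialect is a flat table with comma-separated multi-gene fields;
    the JSON dialect mirrors the same records as a list of objects whose
    multi-gene fields are lists.  Rows violating the schema raise
    :class:`DatabaseError` with a row-addressed message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in TSV_COLUMNS if c not in df.columns and c != "evidence"]
        if missing:
            raise DatabaseError(f"missing column(s): {missing}")
        records = df.to_dict("records")
        interactions = [
            _row_to_interaction(rec, f"row {i + 2}") for i, rec in enumerate(records)
        ]
    elif dialect == "json":
        with open(path) as fh:
            data = json.load(fh)
        interactions = []
        for i, rec in enumerate(data):
            where = f"record {i}"
            for k in ("id", "ligand_subunits", "receptor_subunits"):
                if k not in rec:
                    raise DatabaseError(f"{where}: missing key {k!r}")
            try:
                interactions.append(
                    LRInteraction(
                        id=str(rec["id"]),
                        ligand_subunits=list(rec["ligand_subunits"]),
                        receptor_subunits=list(rec["receptor_subunits"]),
                        agonists=frozenset(rec.get("agonists", [])),
                        antagonists=frozenset(rec.get("antagonists", [])),
                        co_stimulatory=frozenset(rec.get("co_stimulatory", [])),
                        co_inhibitory=frozenset(rec.get("co_inhibitory", [])),
                        pathway=rec.get("pathway", ""),
                        annotation=rec.get("annotation", ""),
                        evidence=rec.get("evidence", ""),
                    )
                )
            except DatabaseError as e:
                raise DatabaseError(f"{where}: {e}") from None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return LRDatabase(interactions)


def write_database(db: LRDatabase, path, dialect: str = "tsv") -> None:
    """Write a database; ``load_database(write_database(db))`` round-trips."""
    path = Path(path)
    if dialect == "tsv":
        rows = []
        for it in db.interactions:
            rows.append(
                {
                    "id": it.id,
                    "ligand_subunits": FIELD_SEP.join(it.ligand_subunits),
                    "receptor_subunits": FIELD_SEP.join(it.receptor_subunits),
                    "agonists": FIELD_SEP.join(sorted(it.agonists)),
                    "antagonists": FIELD_SEP.join(sorted(it.antagonists)),
                    "co_stimulatory": FIELD_SEP.join(sorted(it.co_stimulatory)),
                    "co_inhibitory": FIELD_SEP.join(sorted(it.co_inhibitory)),
                    "pathway": it.pathway,
                    "annotation": it.annotation,
                    "evidence": it.evidence,
                }
            )
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "json":
        data = [
            {
                "id": it.id,
                "ligand_subunits": list(it.ligand_subunits),
                "receptor_subunits": list(it.receptor_subunits),
                "agonists": sorted(it.agonists),
                "antagonists": sorted(it.antagonists),
                "co_stimulatory": sorted(it.co_stimulatory),
                "co_inhibitory": sorted(it.co_inhibitory),
                "pathway": it.pathway,
                "annotation": it.annotation,
                "evidence": it.evidence,
            }
            for it in db.interactions
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def subset_database(
    db: LRDatabase,
    annotation: str | None = None,
    pathways: set[str] | None = None,
) -> LRDatabase:
    """Restrict to interactions matching all supplied filters.

    Derived fields (pathway map, gene universe) are recomputed.
    """
    if annotation is not None and annotation not in ANNOTATION_CLASSES:
        raise DatabaseError(f"unknown annotation class {annotation!r}")
    if pathways is not None:
        unknown = set(pathways) - set(db.pathways)
        if unknown:
            raise DatabaseError(f"unknown pathway label(s): {sorted(unknown)}")
    kept = [
        it
        for it in db.interactions
        if (annotation is None or it.annotation == annotation)
        and (pathways is None or it.pathway in pathways)
    ]
    if not kept:
        raise DatabaseError("no interactions match the requested filters")
    return LRDatabase(kept)


def database_stats(db: LRDatabase) -> dict:
    """Summary counts and fractions for a database."""
    n = len(db)
    by_ann = {a: 0 for a in ANNOTATION_CLASSES}
    n_het = 0
    for it in db.interactions:
        by_ann[it.annotation] += 1
        n_het += it.is_heteromeric
    return {
        "n_interactions": n,
        "annotation_fractions": {a: by_ann[a] / n for a in ANNOTATION_CLASSES},
        "heteromeric_fraction": n_het / n,
        "n_pathways": len(db.pathways),
        "n_genes": len(db.gene_universe),
    }
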