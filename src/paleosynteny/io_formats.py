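"""File formats and dataset-consistency validation.

Reads gene-position tables (GFF3 or TSV) and BLAST tabular HSP files,
and reads/writes the four-sheet submission workbook (contact, genome,
phylogeny, homology-group sheets) in both a tab-delimited text dialect
(one ``.tsv`` per sheet in a directory) and an XLSX mirror.

Coordinates are 1-based inclusive (GFF3 convention); gene ranks are
0-based and dense per chromosome.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "HspRecord",
    "SubmissionWorkbook",
    "Violation",
    "DatasetRegistry",
    "FormatError",
    "read_gene_table",
    "read_blast_tabular",
    "assign_ranks",
    "write_submission_workbook",
    "read_submission_workbook",
    "validate_workbook",
    "write_gene_table",
    "read_lengths_table",
    "write_lengths_table",
]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A gene's genomic placement.

    ``rank`` is the 0-based position of the gene along its chromosome
    after sorting by ``start``; it is dense (0..n-1) per chromosome.
    """

    species: str
    chromosome: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"
    rank: int = -1


@dataclass(frozen=True)
class HspRecord:
    """One BLAST high-scoring pair (local alignment segment)."""

    query_id: str
    subject_id: str
    hsp_length: int
    n_identities: int
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    score: float = 0.0


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_GENE_TSV_COLUMNS = ["gene_id", "species", "chromosome", "start", "end", "strand"]

_GFF3_ID_RE = re.compile(r"(?:^|;)ID=([^;]+)")


def assign_ranks(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort records by (species, chromosome, start) and assign dense ranks.

    Ranks restart at 0 on every (species, chromosome); ties on ``start``
    are broken by ``gene_id`` for determinism.
    """
    ordered = sorted(records, key=lambda g: (g.species, g.chromosome, g.start, g.gene_id))
    out: list[GeneRecord] = []
    prev_key = None
    rank = 0
    for g in ordered:
        key = (g.species, g.chromosome)
        if key != prev_key:
            rank = 0
            prev_key = key
        out.append(dataclasses.replace(g, rank=rank))
        rank += 1
    return out


def _check_unique_ids(records: Sequence[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in records:
        if g.gene_id in seen:
            raise FormatError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    species: str | None = None,
) -> list[GeneRecord]:
    """Read gene positions from a TSV table or a GFF3 file.

    The TSV dialect has a header with columns
    ``gene_id species chromosome start end strand``.  For GFF3, features
    of type ``gene`` are used; the species is taken from the ``species``
    attribute when present, else from the ``species`` argument (required
    otherwise, since GFF3 carries no species column).

    Returns records sorted by (species, chromosome, start) with dense
    0-based ranks per chromosome.
    """
    path = Path(path)
    if dialect == "tsv":
        records = _read_gene_tsv(path)
    elif dialect == "gff3":
        records = _read_gene_gff3(path, species)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    _check_unique_ids(records)
    return assign_ranks(records)


def _read_gene_tsv(path: Path) -> list[GeneRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _GENE_TSV_COLUMNS if c not in df.columns and c != "strand"]
    if missing:
        raise FormatError(f"gene table {path} missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        try:
            start, end = int(d["start"]), int(d["end"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: non-integer coordinate") from exc
        if start > end:
            raise FormatError(f"{path}:{i}: start > end for gene {d['gene_id']!r}")
        records.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                species=str(d["species"]),
                chromosome=str(d["chromosome"]),
                start=start,
                end=end,
                strand=str(d.get("strand", "+") or "+"),
            )
        )
    return records


def _read_gene_gff3(path: Path, default_species: str | None) -> list[GeneRecord]:
    # GFF3 is a 9-column TSV; parsed directly so that errors can carry the
    # offending line number, which column-oriented readers discard.
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            m = _GFF3_ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            sp_m = re.search(r"(?:^|;)species=([^;]+)", attrs)
            sp = sp_m.group(1) if sp_m else default_species
            if sp is None:
                raise FormatError(
                    f"{path}:{lineno}: no species attribute and no species argument given"
                )
            start, end = int(start_s), int(end_s)
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end for gene {m.group(1)!r}")
            records.append(
                GeneRecord(
                    gene_id=m.group(1),
                    species=sp,
                    chromosome=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "+",
                )
            )
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records as the TSV dialect understood by read_gene_table."""
    df = pd.DataFrame(
        [(g.gene_id, g.species, g.chromosome, g.start, g.end, g.strand) for g in records],
        columns=_GENE_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_lengths_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (gene_id, length-in-aa) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "length": int})
    return dict(zip(df["gene_id"], df["length"]))


def write_lengths_table(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(lengths.items()), columns=["gene_id", "length"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

#: Default column layout: BLAST outfmt 6 extended with an identity count
#: (``-outfmt "6 std nident"``).
BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "hsp_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "score",
    "n_identities",
]


def read_blast_tabular(
    path: str | Path, columns: Sequence[str] | None = None
) -> list[HspRecord]:
    """Read tab-separated BLAST output, one HSP per row.

    Self hits (``query_id == subject_id``) are dropped.  Rows violating
    HSP invariants (``n_identities > hsp_length``, non-numeric fields)
    raise :class:`FormatError` with the row number.
    """
    cols = list(columns) if columns is not None else BLAST_COLUMNS
    for required in ("query_id", "subject_id", "hsp_length", "n_identities"):
        if required not in cols:
            raise ValueError(f"column layout lacks required column {required!r}")
    try:
        df = pd.read_csv(path, sep="\t", names=cols, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    out: list[HspRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        if d["query_id"] == d["subject_id"]:
            continue
        try:
            length = int(d["hsp_length"])
            nid = int(d["n_identities"])
            score = float(d.get("score", 0) or 0)
            qs = int(float(d.get("query_start", 0) or 0))
            qe = int(float(d.get("query_end", 0) or 0))
            ss = int(float(d.get("subject_start", 0) or 0))
            se = int(float(d.get("subject_end", 0) or 0))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: non-numeric field") from exc
        if length < 1:
            raise FormatError(f"{path} row {i}: hsp_length < 1")
        if not 0 <= nid <= length:
            raise FormatError(
                f"{path} row {i}: n_identities={nid} outside [0, hsp_length={length}]"
            )
        out.append(
            HspRecord(
                query_id=str(d["query_id"]),
                subject_id=str(d["subject_id"]),
                hsp_length=length,
                n_identities=nid,
                query_start=qs,
                query_end=qe,
                subject_start=ss,
                subject_end=se,
                score=score,
            )
        )
    return out


def write_blast_tabular(hsps: Sequence[HspRecord], path: str | Path) -> None:
    """Write HSPs in the default extended-outfmt-6 layout."""
    rows = []
    for h in hsps:
        pid = 100.0 * h.n_identities / h.hsp_length
        rows.append(
            (
                h.query_id,
                h.subject_id,
                f"{pid:.2f}",
                h.hsp_length,
                h.hsp_length - h.n_identities,
                0,
                h.query_start,
                h.query_end,
                h.subject_start,
                h.subject_end,
                0.0,
                h.score,
                h.n_identities,
            )
        )
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Submission workbook
# ---------------------------------------------------------------------------

SHEET_NAMES = ("CONTACT", "GENOME", "PHYLOGENY", "HOMOLOGY_GROUP")

CONTACT_COLUMNS = ["key", "value"]
GENOME_COLUMNS = [
    "gene_id",
    "species",
    "genome_version",
    "chromosome",
    "start",
    "end",
    "strand",
]
PHYLOGENY_COLUMNS = ["species", "chromosome", "car_id"]
HOMOLOGY_COLUMNS = [
    "pg_id",
    "car_id",
    "ancestral_rank",
    "status",
    "species",
    "gene_id",
    "backfilled",
]


@dataclass
class SubmissionWorkbook:
    """The four-sheet data-exchange workbook.

    Sheets are plain DataFrames with artifact-defined columns (the public
    template's headers are not standardized; the mapping is documented in
    the README).  ``dataset_name`` and ``version`` are serialized as rows
    of the contact sheet.
    """

    contact_sheet: pd.DataFrame
    genome_sheet: pd.DataFrame
    phylogeny_sheet: pd.DataFrame
    homology_sheet: pd.DataFrame
    dataset_name: str = "dataset"
    version: int = 1

    def sheets(self) -> dict[str, pd.DataFrame]:
        return {
            "CONTACT": self.contact_sheet,
            "GENOME": self.genome_sheet,
            "PHYLOGENY": self.phylogeny_sheet,
            "HOMOLOGY_GROUP": self.homology_sheet,
        }


@dataclass(frozen=True)
class Violation:
    """One dataset-consistency violation (data, not an exception)."""

    kind: str
    subject: str
    message: str


def build_submission_workbook(
    karyotype,
    genes: Sequence[GeneRecord],
    meta: Mapping[str, str] | None = None,
    dataset_name: str = "dataset",
    version: int = 1,
    genome_version: str = "1.0",
) -> SubmissionWorkbook:
    """Assemble the four sheets from a reconstructed karyotype.

    Raises :class:`FormatError` if a protogene member gene is absent from
    ``genes`` (referential integrity is enforced at write time).
    """
    meta = dict(meta or {})
    known = {g.gene_id for g in genes}
    for pg in karyotype.protogenes.values():
        for sp, members in pg.members.items():
            for gid in members:
                if gid not in known:
                    raise FormatError(
                        f"protogene {pg.pg_id} member {gid!r} absent from gene table"
                    )

    contact_rows = [("dataset_name", dataset_name), ("version", str(version))]
    contact_rows += sorted(meta.items())
    contact = pd.DataFrame(contact_rows, columns=CONTACT_COLUMNS)

    genome = pd.DataFrame(
        [
            (g.gene_id, g.species, genome_version, g.chromosome, g.start, g.end, g.strand)
            for g in genes
        ],
        columns=GENOME_COLUMNS,
    )

    phylo_rows = []
    for car in karyotype.cars:
        for sp, segments in sorted(car.derived_segments.items()):
            for chrom, _lo, _hi in segments:
                phylo_rows.append((sp, chrom, car.car_id))
    phylogeny = (
        pd.DataFrame(sorted(set(phylo_rows)), columns=PHYLOGENY_COLUMNS)
        if phylo_rows
        else pd.DataFrame(columns=PHYLOGENY_COLUMNS)
    )

    hom_rows = []
    for pg in karyotype.protogenes.values():
        rank = "" if pg.ancestral_rank is None else pg.ancestral_rank
        for sp in sorted(pg.members):
            for gid in pg.members[sp]:
                hom_rows.append(
                    (
                        pg.pg_id,
                        pg.car_id or "",
                        rank,
                        pg.status or "",
                        sp,
                        gid,
                        int(gid in pg.backfilled),
                    )
                )
    homology = pd.DataFrame(hom_rows, columns=HOMOLOGY_COLUMNS)

    return SubmissionWorkbook(
        contact_sheet=contact,
        genome_sheet=genome,
        phylogeny_sheet=phylogeny,
        homology_sheet=homology,
        dataset_name=dataset_name,
        version=version,
    )


def write_submission_workbook(wb: SubmissionWorkbook, path: str | Path) -> None:
    """Write the workbook.

    A path ending in ``.xlsx`` produces a spreadsheet; any other path is
    treated as a directory receiving one ``<SHEET>.tsv`` per sheet (the
    canonical text dialect).
    """
    path = Path(path)
    if path.suffix == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, df in wb.sheets().items():
                df.to_excel(writer, sheet_name=name, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, df in wb.sheets().items():
            df.to_csv(path / f"{name}.tsv", sep="\t", index=False)


def read_submission_workbook(path: str | Path) -> SubmissionWorkbook:
    """Read a workbook written by :func:`write_submission_workbook`."""
    path = Path(path)
    sheets: dict[str, pd.DataFrame] = {}
    if path.suffix == ".xlsx":
        raw = pd.read_excel(path, sheet_name=None, dtype=str)
        for name in SHEET_NAMES:
            if name not in raw:
                raise FormatError(f"workbook {path} missing sheet {name}")
            sheets[name] = raw[name].fillna("")
    else:
        for name in SHEET_NAMES:
            fp = path / f"{name}.tsv"
            if not fp.exists():
                raise FormatError(f"workbook {path} missing sheet file {fp.name}")
            try:
                sheets[name] = pd.read_csv(fp, sep="\t", dtype=str).fillna("")
            except pd.errors.EmptyDataError:
                sheets[name] = pd.DataFrame()
    contact = sheets["CONTACT"]
    kv = dict(zip(contact.get("key", []), contact.get("value", [])))
    # normalize numeric columns read back as strings
    genome = sheets["GENOME"]
    for col in ("start", "end"):
        if col in genome.columns:
            genome[col] = genome[col].astype(int)
    homology = sheets["HOMOLOGY_GROUP"]
    if "backfilled" in homology.columns and len(homology):
        homology["backfilled"] = homology["backfilled"].astype(int)
    return SubmissionWorkbook(
        contact_sheet=contact,
        genome_sheet=genome,
        phylogeny_sheet=sheets["PHYLOGENY"],
        homology_sheet=homology,
        dataset_name=kv.get("dataset_name", "dataset"),
        version=int(kv.get("version", 1)),
    )


def validate_workbook(
    wb: SubmissionWorkbook,
    existing_versions: Mapping[str, int] | None = None,
) -> list[Violation]:
    """Enumerate every consistency violation; an empty report means loadable.

    Checks unicity of gene identifiers, dangling references from the
    homology and phylogeny sheets into the genome sheet, duplicate
    homology memberships, and version conflicts against
    ``existing_versions`` (dataset name -> highest loaded version).
    """
    violations: list[Violation] = []
    genome = wb.genome_sheet
    gene_ids = list(genome["gene_id"]) if "gene_id" in genome.columns else []
    seen: set[str] = set()
    for gid in gene_ids:
        if gid in seen:
            violations.append(
                Violation("duplicate_gene_id", gid, f"gene_id {gid!r} occurs more than once")
            )
        seen.add(gid)

    known_chroms = (
        set(zip(genome["species"], genome["chromosome"]))
        if {"species", "chromosome"} <= set(genome.columns)
        else set()
    )
    phylo = wb.phylogeny_sheet
    if {"species", "chromosome"} <= set(phylo.columns):
        for sp, chrom in zip(phylo["species"], phylo["chromosome"]):
            if (sp, chrom) not in known_chroms:
                violations.append(
                    Violation(
                        "unknown_chromosome",
                        f"{sp}:{chrom}",
                        f"phylogeny sheet references unknown chromosome {chrom!r} of {sp!r}",
                    )
                )

    hom = wb.homology_sheet
    if "gene_id" in hom.columns:
        seen_members: set[tuple[str, str]] = set()
        for pg_id, gid in zip(hom["pg_id"], hom["gene_id"]):
            if gid not in seen:
                violations.append(
                    Violation(
                        "unknown_gene",
                        gid,
                        f"homology sheet references unknown gene {gid!r}",
                    )
                )
            if (pg_id, gid) in seen_members:
                violations.append(
                    Violation(
                        "duplicate_membership",
                        f"{pg_id}/{gid}",
                        f"gene {gid!r} listed twice in group {pg_id!r}",
                    )
                )
            seen_members.add((pg_id, gid))

    if existing_versions is not None:
        have = existing_versions.get(wb.dataset_name)
        if have is not None and wb.version <= have:
            violations.append(
                Violation(
                    "version_conflict",
                    wb.dataset_name,
                    f"dataset {wb.dataset_name!r} version {wb.version} already loaded "
                    f"(latest {have})",
                )
            )
    return violations


class DatasetRegistry:
    """Tracks loaded (dataset, version) pairs; loading v+1 obsoletes v."""

    def __init__(self) -> None:
        self._versions: dict[str, list[int]] = {}

    @property
    def latest(self) -> dict[str, int]:
        return {k: max(v) for k, v in self._versions.items() if v}

    def load(self, wb: SubmissionWorkbook) -> None:
        report = validate_workbook(wb, existing_versions=self.latest)
        if report:
            raise FormatError(
                "refusing to load inconsistent workbook: "
                + "; ".join(v.message for v in report)
            )
        self._versions.setdefault(wb.dataset_name, []).append(wb.version)

    def obsolete_versions(self, dataset_name: str) -> list[int]:
        versions = sorted(self._versions.get(dataset_name, []))
        return versions[:-1]

    def current_version(self, dataset_name: str) -> int | None:
        versions = self._versions.get(dataset_name)
        return max(versions) if versions else None
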