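"""Pipeline configuration and readers/writers for every external format.

All genomic intervals inside the package are 0-based half-open on the
subject plus strand, with strand carried separately.  The tabular hit
format is BLAST "outfmt 6" extended with ``qlen`` and ``nident``; the
spacer table is modeled on CRISPRCasdb-style exports (``Spacers``,
``Repeats``, ``Accessionnrs`` columns plus free metadata).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from ._seq import normalize_sequence

logger = logging.getLogger("spacerscope")

#: column order of the extended tabular hit format
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "nident",
]

#: controlled vocabulary of CRISPR-Cas subtype labels
SUBTYPE_VOCABULARY = frozenset(
    [f"I-{c}" for c in "ABCDEFG"]
    + [f"II-{c}" for c in "ABC"]
    + [f"III-{c}" for c in "ABCD"]
    + ["III", "IV", "V", "VI"]
)

#: taxonomy ranks recognized as spacer-table columns
TAXONOMY_RANKS = ["Genus", "Family", "Order", "Class", "Phylum", "Superkingdom"]


class SchemaError(ValueError):
    """A table is missing a mandatory column or has a malformed row."""


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, in one place.

    Defaults are the values used throughout the analysis: the two-step
    matched-fraction filter (90% then 80%), the 27-nt minimum spacer
    length, the 13-identity array-hit test with -3/-3 gap penalties,
    90% repeat clustering and 74% subtype-inference identity, the
    10-unique-protospacer floor, the 0.3-bit/5x-median orientation and
    0.5-bit/10x-median PAM thresholds, a minimum PAM size of 2 nt, the
    25-kb array-to-cas-cluster proximity window and alpha = 0.01.
    """

    flank_len: int = 23
    step1_frac: float = 0.90
    step2_frac: float = 0.80
    min_spacer_len: int = 27
    array_gap_open: float = -3.0
    array_gap_extend: float = -3.0
    array_identity_min: int = 13          # exclusive: > 13 identities flags an array hit
    repeat_cluster_identity: float = 0.90
    subtype_identity: float = 0.74
    min_protospacers: int = 10
    orient_bits_min: float = 0.3
    orient_median_factor: float = 5.0
    pam_bits_min: float = 0.5
    pam_median_factor: float = 10.0
    pam_min_size: int = 2
    proximity_bp: int = 25000
    alpha: float = 0.01
    seed_word: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step1_frac", "step2_frac", "repeat_cluster_identity",
                     "subtype_identity", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.step2_frac >= self.step1_frac:
            raise ValueError("step2_frac must be < step1_frac")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if self.pam_min_size < 1:
            raise ValueError("pam_min_size must be >= 1")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the configuration, used in run logging."""
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SpacerRecord:
    """One spacer with its repeat and host/array context."""

    spacer_id: str
    sequence: str
    repeat: str
    host_accession: str
    genus: str | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)
    array_id: str | None = None
    position_in_array: int | None = None
    subtype: str | None = None
    cas_genes: frozenset[str] = frozenset()
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass
class SubjectSequence:
    """One candidate target sequence (contig/genome/metagenome fragment)."""

    subject_id: str
    sequence: str
    source_class: str = "nucleotide_db"   # nucleotide_db | metagenome | synthetic

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """A CDS/ORF interval, 0-based half-open on the plus strand."""

    subject_id: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad ORF interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SPACER_ALIASES = {
    "spacer": ["Spacers", "spacer", "spacer_seq", "sequence"],
    "repeat": ["Repeats", "repeat", "repeat_seq"],
    "accession": ["Accessionnrs", "accession", "host_accession"],
}
_OPTIONAL_ALIASES = {
    "spacer_id": ["spacer_id", "id"],
    "genus": ["Genus", "genus"],
    "array_id": ["array_id", "Array"],
    "position_in_array": ["position_in_array", "position"],
    "subtype": ["Subtype", "subtype"],
    "cas_genes": ["cas_genes", "Cas_genes"],
}


def _find_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lower = {c.lower(): c for c in columns}
    for a in aliases:
        if a.lower() in lower:
            return lower[a.lower()]
    return None


def read_spacer_table(path: str | Path, dialect: str | None = None) -> list[SpacerRecord]:
    """Read a CRISPRCasdb-style delimited spacer table.

    ``dialect`` may be ``'csv'`` or ``'tsv'``; by default the separator is
    sniffed from the header line.  Mandatory columns (any alias casing):
    spacer, repeat, accession.  Unknown columns are preserved verbatim in
    :attr:`SpacerRecord.metadata`.
    """
    path = Path(path)
    if dialect == "tsv":
        sep = "\t"
    elif dialect == "csv":
        sep = ","
    else:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    cols: dict[str, str] = {}
    for key, aliases in _SPACER_ALIASES.items():
        col = _find_column(df.columns, aliases)
        if col is None:
            raise SchemaError(f"spacer table is missing mandatory column {aliases[0]!r}")
        cols[key] = col
    opt = {k: _find_column(df.columns, v) for k, v in _OPTIONAL_ALIASES.items()}
    tax_cols = {r: c for r in TAXONOMY_RANKS if (c := _find_column(df.columns, [r]))}
    claimed = set(cols.values()) | {c for c in opt.values() if c} | set(tax_cols.values())

    records: list[SpacerRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = dict(zip(df.columns, row))
        try:
            seq, amb1 = normalize_sequence(row[cols["spacer"]])
            rep, amb2 = normalize_sequence(row[cols["repeat"]])
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
        if amb1 or amb2:
            warnings.warn(f"row {i}: ambiguity codes mapped to N", stacklevel=2)
        spacer_id = row[opt["spacer_id"]] if opt["spacer_id"] else f"sp{i - 2:06d}"
        if spacer_id in seen_ids:
            raise SchemaError(f"row {i}: duplicate spacer_id {spacer_id!r}")
        seen_ids.add(spacer_id)
        genus = row[opt["genus"]] if opt["genus"] else None
        taxonomy = {r: row[c] for r, c in tax_cols.items() if row[c]}
        if genus is None and "Genus" in taxonomy:
            genus = taxonomy["Genus"]
        cas_raw = row[opt["cas_genes"]] if opt["cas_genes"] else ""
        cas = frozenset(t.strip() for t in cas_raw.split(";") if t.strip())
        pos = row[opt["position_in_array"]] if opt["position_in_array"] else None
        records.append(
            SpacerRecord(
                spacer_id=spacer_id,
                sequence=seq,
                repeat=rep,
                host_accession=row[cols["accession"]],
                genus=genus or None,
                taxonomy=taxonomy,
                array_id=row[opt["array_id"]] if opt["array_id"] else None,
                position_in_array=int(pos) if pos not in (None, "") else None,
                subtype=(row[opt["subtype"]] or None) if opt["subtype"] else None,
                cas_genes=cas,
                metadata={c: row[c] for c in df.columns if c not in claimed},
            )
        )
    return records


def write_spacer_table(records: Iterable[SpacerRecord], path: str | Path) -> None:
    """Write records in the same dialect :func:`read_spacer_table` accepts."""
    rows = []
    for r in records:
        row = {
            "spacer_id": r.spacer_id,
            "Spacers": r.sequence,
            "Repeats": r.repeat,
            "Accessionnrs": r.host_accession,
            "Genus": r.genus or "",
            "array_id": r.array_id or "",
            "position_in_array": "" if r.position_in_array is None else r.position_in_array,
            "Subtype": r.subtype or "",
            "cas_genes": ";".join(sorted(r.cas_genes)),
        }
        for rank, name in r.taxonomy.items():
            if rank != "Genus":
                row[rank] = name
        row.update(r.metadata)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta(path: str | Path, default_class: str = "nucleotide_db") -> list[SubjectSequence]:
    """Read subjects from FASTA; ids are taken up to the first whitespace.

    A ``class=<label>`` token in the description sets ``source_class``.
    Duplicate ids are an error; an empty file yields an empty list with a
    warning.
    """
    subjects: list[SubjectSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        source = default_class
        for token in rec.description.split():
            if token.startswith("class="):
                source = token.split("=", 1)[1]
        seq, _ = normalize_sequence(str(rec.seq))
        subjects.append(SubjectSequence(rec.id, seq, source))
    if not subjects:
        warnings.warn(f"no sequences in {path}", stacklevel=2)
    return subjects


def write_fasta(subjects: Iterable[SubjectSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in subjects:
            fh.write(f">{s.subject_id} class={s.source_class}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read an extended BLAST outfmt-6 style hit table.

    Requires the 12 standard columns plus ``qlen`` and ``nident`` (with or
    without a header line).  Returns a DataFrame with subject coordinates
    converted to 0-based half-open plus-strand ``s_start``/``s_end`` and an
    inferred ``strand`` column (minus when sstart > send).
    """
    path = Path(path)
    first = path.open().readline()
    has_header = first.split("\t")[0].strip().lower() in ("qseqid", "#qseqid")
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if not has_header:
        if df.shape[1] != len(HIT_COLUMNS):
            raise SchemaError(
                f"hit table has {df.shape[1]} columns; expected the 12 standard "
                "outfmt-6 columns extended with qlen and nident "
                f"({' '.join(HIT_COLUMNS)})"
            )
        df.columns = HIT_COLUMNS
    missing = [c for c in ("qlen", "nident") if c not in df.columns]
    if missing:
        raise SchemaError(
            f"hit table is missing required extension column(s) {missing}; "
            "re-run the search with -outfmt '6 "
            + " ".join(HIT_COLUMNS) + "'"
        )
    minus = df["sstart"] > df["send"]
    lo = df[["sstart", "send"]].min(axis=1)
    hi = df[["sstart", "send"]].max(axis=1)
    df = df.assign(
        strand=pd.Series("-", index=df.index).where(minus, "+"),
        s_start=lo - 1,
        s_end=hi,
    )
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write hits back in the extended tabular format (internal -> 1-based)."""
    out = df.copy()
    plus = out["strand"] == "+"
    out["sstart"] = (out["s_start"] + 1).where(plus, out["s_end"])
    out["send"] = out["s_end"].where(plus, out["s_start"] + 1)
    out[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gff(path: str | Path) -> list[OrfAnnotation]:
    """Extract CDS features from a GFF3 file.

    1-based closed coordinates become 0-based half-open.  Malformed lines
    raise :class:`SchemaError` naming the line number; a file without CDS
    features returns an empty list with a warning.
    """
    orfs: list[OrfAnnotation] = []
    any_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise SchemaError(f"{path}:{lineno}: expected >= 8 GFF3 fields")
            any_feature = True
            if parts[2] != "CDS":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if parts[6] not in "+-":
                raise SchemaError(f"{path}:{lineno}: bad strand {parts[6]!r}")
            orfs.append(OrfAnnotation(parts[0], start - 1, end, parts[6]))
    if any_feature and not orfs:
        warnings.warn(f"no CDS features in {path}", stacklevel=2)
    return orfs


def write_gff(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, orf in enumerate(orfs):
            fh.write(
                f"{orf.subject_id}\tspacerscope\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\tID=cds{i}\n"
            )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_pam_catalog(calls: Iterable, path: str | Path) -> None:
    """Write a PAM catalog with columns repeat,PAM,subtype."""
    rows = [
        {"repeat": c.representative_repeat, "PAM": c.motif, "subtype": c.subtype or ""}
        for c in calls
    ]
    pd.DataFrame(rows, columns=["repeat", "PAM", "subtype"]).to_csv(path, index=False)


def write_spacer_annotations(rows: Iterable[Mapping], path: str | Path) -> None:
    """Per-spacer annotation table.

    ``orientation_PAMbased`` and ``strand_call`` use the {1, 0, -1}
    encoding (1 coding strand, 0 template strand, -1 undetermined); an
    ``undetermined_reason`` column disambiguates intergenic hits from
    unresolved orientations.
    """
    columns = [
        "spacer", "repeat", "accession", "subtype", "hit", "repeat_cluster",
        "orientation_PAMbased", "strand_call", "PAM", "undetermined_reason",
    ]
    df = pd.DataFrame(list(rows))
    for c in columns:
        if c not in df.columns:
            df[c] = ""
    df[columns].to_csv(path, index=False)


def write_compatibility_table(calls: Iterable, path: str | Path) -> None:
    """Write compatibility calls: accession, subtypes, PAM, category."""
    rows = [
        {
            "accession": c.host_accession,
            "subtypes": "+".join(c.subtype_pair) if c.subtype_pair else "",
            "PAM": c.shared_pam or "",
            "category": c.category,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["accession", "subtypes", "PAM", "category"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_hit_fractions(
    records: Sequence[SpacerRecord],
    hit_spacer_ids: Iterable[str],
    group_by: str = "subtype",
    min_group_size: int = 1,
) -> pd.DataFrame:
    """Fraction of spacers with at least one kept hit, per group.

    ``group_by`` is ``'subtype'``, ``'genus'`` or a taxonomy rank present in
    the records.  Groups below ``min_group_size`` are flagged, never
    silently dropped; empty groups are never emitted.
    """
    if group_by not in ("subtype", "genus") and group_by not in TAXONOMY_RANKS:
        raise KeyError(f"unknown group key {group_by!r}")

    def key(r: SpacerRecord) -> str | None:
        if group_by == "subtype":
            return r.subtype
        if group_by == "genus":
            return r.genus
        if group_by in TAXONOMY_RANKS:
            return r.taxonomy.get(group_by)
        raise KeyError(f"unknown group key {group_by!r}")

    with_hit = set(hit_spacer_ids)
    groups: dict[str, list[SpacerRecord]] = {}
    for r in records:
        k = key(r)
        if k is not None:
            groups.setdefault(k, []).append(r)
    rows = []
    for name in sorted(groups):
        members = groups[name]
        n = len(members)
        n_hit = sum(1 for r in members if r.spacer_id in with_hit)
        rows.append(
            {
                "group": name,
                "n_spacers": n,
                "n_with_hit": n_hit,
                "fraction": n_hit / n,
                "small_group": n < min_group_size,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_spacers", "n_with_hit", "fraction", "small_group"])
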