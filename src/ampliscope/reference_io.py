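"""Reference-database and query I/O with multi-dialect taxonomy parsing.

Reference databases arrive as FASTA with a rank-delimited lineage string
either embedded in the header or supplied as a sidecar TSV.  The three
database families format that string differently:

* ``qiime-generic`` / ``greengenes2`` — ``d__Bacteria; p__...; s__Genus_species``
* ``silva`` — plain semicolon path, ranks assigned positionally domain→species
* ``rdp`` — ``Root;``-prefixed semicolon path, domain→species

All dialects are normalized onto one :class:`TaxonomyLineage` so that
species-level accuracy can be scored in a single key space regardless of the
source database.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

_QIIME_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

DIALECTS = ("qiime-generic", "greengenes2", "silva", "rdp", "none")

#: tokens that mark a species name as vague / non-standard (lower-cased)
DEFAULT_NAME_BLACKLIST: frozenset[str] = frozenset({
    "sp.", "sp", "spp.", "spp", "uncultured", "unidentified", "unclassified",
    "bacterium", "candidatus", "candidate", "metagenome", "environmental",
})


class FastaParseError(ValueError):
    """Malformed FASTA input (empty id, missing sequence, duplicate id)."""


class TaxonomyParseError(ValueError):
    """A lineage string that does not parse under the declared dialect."""


_STRAIN_SUFFIX = re.compile(r"\s+(str\.?|strain|subsp\.?|var\.?|bv\.?)\s.*$",
                            re.IGNORECASE)


def normalize_species(name: str) -> str:
    """Normalize a species label to a bare binomial.

    Underscores become spaces, whitespace is collapsed, and anything after
    the binomial (strain designations, serovar tags, ...) is stripped.
    Matching downstream is case-insensitive on this normalized form.
    """
    s = name.replace("_", " ").strip()
    s = re.sub(r"\s+", " ", s)
    if not s:
        return ""
    s = _STRAIN_SUFFIX.sub("", s)
    tokens = s.split(" ")
    if len(tokens) >= 2:
        return f"{tokens[0]} {tokens[1]}"
    return tokens[0]


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered domain→species lineage.

    ``taxa`` is a prefix of the seven canonical ranks: missing tail ranks are
    allowed (a genus-level record has ``len(taxa) == 6``), missing interior
    ranks are not representable.
    """

    taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.taxa) > len(RANKS):
            raise ValueError(f"lineage has {len(self.taxa)} ranks; max {len(RANKS)}")
        for t in self.taxa:
            if not str(t):
                raise ValueError("interior lineage ranks must be non-empty")

    def __len__(self) -> int:
        return len(self.taxa)

    def rank(self, rank_name: str) -> str | None:
        i = RANKS.index(rank_name)
        return self.taxa[i] if i < len(self.taxa) else None

    @property
    def species(self) -> str | None:
        return self.rank("species")

    @property
    def genus(self) -> str | None:
        return self.rank("genus")

    @property
    def normalized_species(self) -> str:
        sp = self.species
        return normalize_species(sp) if sp else ""

    def truncate(self, depth: int) -> "TaxonomyLineage":
        """Keep the first ``depth`` ranks (0 = unclassified)."""
        return TaxonomyLineage(self.taxa[:depth])

    def agrees_at(self, other: "TaxonomyLineage", depth: int) -> bool:
        """True when both lineages carry identical taxa through rank ``depth``
        (0-based rank index); species rank compares on the normalized binomial."""
        if len(self.taxa) <= depth or len(other.taxa) <= depth:
            return False
        for i in range(depth + 1):
            a, b = self.taxa[i], other.taxa[i]
            if i == RANKS.index("species"):
                if normalize_species(a).lower() != normalize_species(b).lower():
                    return False
            elif a != b:
                return False
        return True

    # -- dialect rendering ------------------------------------------------
    def to_string(self, dialect: str = "qiime-generic") -> str:
        if dialect in ("qiime-generic", "greengenes2"):
            parts = []
            for i, t in enumerate(self.taxa):
                parts.append(f"{_QIIME_PREFIXES[i]}{t.replace(' ', '_')}")
            return "; ".join(parts)
        if dialect == "silva":
            return ";".join(self.taxa)
        if dialect == "rdp":
            return "Root;" + ";".join(self.taxa)
        if dialect == "none":
            return ""
        raise ValueError(f"unknown taxonomy dialect: {dialect!r}")

    def key(self) -> str:
        """Canonical string key (used as the classifier class label)."""
        return ";".join(self.taxa)

    @staticmethod
    def from_key(key: str) -> "TaxonomyLineage":
        return TaxonomyLineage(tuple(t for t in key.split(";") if t))


def parse_lineage(text: str, dialect: str) -> TaxonomyLineage:
    """Parse one lineage string under the given dialect.

    Raises :class:`TaxonomyParseError` on unknown prefixes or layouts; callers
    that read whole files downgrade that to a per-record warning.
    """
    text = text.strip()
    if dialect == "none" or not text:
        return TaxonomyLineage()
    if dialect in ("qiime-generic", "greengenes2"):
        parts = [p.strip() for p in text.split(";")]
        taxa: list[str] = []
        for i, part in enumerate(parts):
            if i >= len(RANKS):
                raise TaxonomyParseError(f"more than {len(RANKS)} ranks: {text!r}")
            if not part.startswith(_QIIME_PREFIXES[i]):
                raise TaxonomyParseError(
                    f"expected prefix {_QIIME_PREFIXES[i]!r} at rank "
                    f"{RANKS[i]!r}: {part!r}")
            name = part[len(_QIIME_PREFIXES[i]):].replace("_", " ").strip()
            if not name:
                break  # empty placeholder ends the lineage
            taxa.append(name)
        return TaxonomyLineage(tuple(taxa))
    if dialect == "silva":
        parts = [p.strip() for p in text.split(";") if p.strip()]
        if len(parts) > len(RANKS):
            raise TaxonomyParseError(f"more than {len(RANKS)} ranks: {text!r}")
        return TaxonomyLineage(tuple(parts))
    if dialect == "rdp":
        if not text.startswith("Root;"):
            raise TaxonomyParseError(f"RDP lineage must start with 'Root;': {text!r}")
        parts = [p.strip() for p in text[len("Root;"):].split(";") if p.strip()]
        if len(parts) > len(RANKS):
            raise TaxonomyParseError(f"more than {len(RANKS)} ranks: {text!r}")
        return TaxonomyLineage(tuple(parts))
    raise ValueError(f"unknown taxonomy dialect: {dialect!r}")


@dataclass
class ReferenceRecord:
    id: str
    sequence: str
    lineage: TaxonomyLineage = field(default_factory=TaxonomyLineage)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ParseReport:
    n_records: int = 0
    n_taxonomy_failures: int = 0
    failed_ids: list[str] = field(default_factory=list)


@dataclass
class ReferenceDatabase:
    name: str
    records: list[ReferenceRecord] = field(default_factory=list)
    dialect: str = "qiime-generic"
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1} if len(ids) != len(set(ids)) else set()
        if dup:
            raise FastaParseError(
                f"duplicate record id(s) in database {self.name!r}: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def species(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for r in self.records:
            sp = r.lineage.normalized_species
            if sp and sp.lower() not in seen:
                seen.add(sp.lower())
                out.append(sp)
        return out


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(
    path: str | Path,
    dialect: str = "qiime-generic",
    name: str | None = None,
    taxonomy_tsv: str | Path | None = None,
) -> ReferenceDatabase:
    """Read a (possibly gzipped) FASTA into a :class:`ReferenceDatabase`.

    Taxonomy comes from the header description under ``dialect``, or — when
    ``taxonomy_tsv`` is given — from a two-column ``id<TAB>lineage`` sidecar.
    Unparseable lineages yield a per-record warning and an empty lineage,
    counted in ``db.report``; structurally malformed FASTA raises
    :class:`FastaParseError` with a line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar: dict[str, str] = {}
    if taxonomy_tsv is not None:
        with _open_text(taxonomy_tsv) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                rid, _, lin = line.partition("\t")
                sidecar[rid] = lin

    with _open_text(path) as fh:
        text = fh.read()
    _validate_fasta_structure(text, path)

    report = ParseReport()
    records: list[ReferenceRecord] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen_ids:
            raise FastaParseError(f"duplicate record id {rec.id!r} in {path}")
        seen_ids.add(rec.id)
        if taxonomy_tsv is not None:
            lin_text = sidecar.get(rec.id, "")
        else:
            lin_text = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            lineage = parse_lineage(lin_text, dialect)
        except TaxonomyParseError as exc:
            warnings.warn(f"record {rec.id!r}: {exc}", stacklevel=2)
            lineage = TaxonomyLineage()
            report.n_taxonomy_failures += 1
            report.failed_ids.append(rec.id)
        records.append(ReferenceRecord(rec.id, str(rec.seq), lineage))
        report.n_records += 1

    return ReferenceDatabase(
        name=name or path.stem, records=records, dialect=dialect, report=report)


def _validate_fasta_structure(text: str, path: Path) -> None:
    """Reject headers with empty ids or records with no sequence, naming lines."""
    header_line: int | None = None
    has_seq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            if header_line is not None and not has_seq:
                raise FastaParseError(
                    f"{path}: record at line {header_line} has no sequence")
            if not line[1:].strip():
                raise FastaParseError(f"{path}: empty record id at line {lineno}")
            header_line, has_seq = lineno, False
        elif line.strip():
            if header_line is None:
                raise FastaParseError(
                    f"{path}: sequence before any header at line {lineno}")
            has_seq = True
    if header_line is not None and not has_seq:
        raise FastaParseError(f"{path}: record at line {header_line} has no sequence")


def write_fasta(db: ReferenceDatabase, path: str | Path, line_width: int = 0) -> None:
    """Write a database back to FASTA, lineage rendered in the db's dialect.

    ``line_width=0`` writes single-line sequences (the round-trip-stable form).
    """
    with _open_text(path, "wt") as fh:
        for rec in db.records:
            lin = rec.lineage.to_string(db.dialect)
            header = f">{rec.id} {lin}".rstrip()
            fh.write(header + "\n")
            if line_width and line_width > 0:
                for i in range(0, len(rec.sequence), line_width):
                    fh.write(rec.sequence[i:i + line_width] + "\n")
            else:
                fh.write(rec.sequence + "\n")


def write_query_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for qid, seq in seqs.items():
            fh.write(f">{qid}\n{seq}\n")


def read_query_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Record filters
# ---------------------------------------------------------------------------

def deduplicate(db: ReferenceDatabase, min_length: int = 200
                ) -> tuple[ReferenceDatabase, dict[str, int]]:
    """Drop short records and duplicate accessions/sequences.

    Records shorter than ``min_length`` (default 200 bp) are removed; among
    records sharing an id or an exact (upper-cased) sequence string, the first
    in input order is kept.  Returns the filtered database plus a count of
    removals per reason.
    """
    report = {"short": 0, "duplicate_id": 0, "duplicate_sequence": 0}
    seen_ids: set[str] = set()
    seen_seqs: set[str] = set()
    kept: list[ReferenceRecord] = []
    for rec in db.records:
        if len(rec) < min_length:
            report["short"] += 1
            continue
        if rec.id in seen_ids:
            report["duplicate_id"] += 1
            continue
        if rec.sequence in seen_seqs:
            report["duplicate_sequence"] += 1
            continue
        seen_ids.add(rec.id)
        seen_seqs.add(rec.sequence)
        kept.append(rec)
    out = ReferenceDatabase(name=db.name, records=kept, dialect=db.dialect)
    return out, report


def length_filter(seqs: Iterable, min_bp: int, max_bp: int):
    """Partition sequences into (kept, removed) by length window [min_bp, max_bp].

    Accepts strings, (id, seq) pairs, or objects with ``__len__``.
    """
    if min_bp > max_bp:
        raise ValueError(f"min_bp {min_bp} > max_bp {max_bp}")
    kept, removed = [], []
    for s in seqs:
        n = len(s[1]) if isinstance(s, tuple) else len(s)
        (kept if min_bp <= n <= max_bp else removed).append(s)
    return kept, removed


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment hit (BLAST outfmt-6 style)."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    subject_species: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of [0,100]: {self.percent_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


def read_blast_tsv(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST outfmt-6 TSV (cols 1,2,3,11 used; optional 13th
    column is taken as the subject title / species name)."""
    hits: list[AlignmentHit] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"expected ≥12 columns, got {len(cols)}: {line!r}")
            hits.append(AlignmentHit(
                query_id=cols[0], subject_id=cols[1],
                percent_identity=float(cols[2]), evalue=float(cols[10]),
                subject_species=cols[12] if len(cols) > 12 else ""))
    return hits


def _species_name_ok(name: str, blacklist: frozenset[str]) -> bool:
    name = name.strip()
    if not name:
        return False
    if name.startswith("[") or name.startswith("("):
        return False
    tokens = [t.lower() for t in name.replace("_", " ").split()]
    return not any(t in blacklist for t in tokens)


def filter_annotations(
    hits: Sequence[AlignmentHit],
    max_evalue: float = 1e-10,
    min_identity: float = 99.0,
    blacklist: frozenset[str] = DEFAULT_NAME_BLACKLIST,
    discard_logic: str = "or",
) -> list[AlignmentHit]:
    """Apply the annotation quality filter to alignment hits.

    With ``discard_logic="or"`` (default) a hit is discarded when it fails
    *either* threshold (e-value > max_evalue or identity < min_identity);
    ``"and"`` discards only when both fail.  Hits whose species name is empty
    or contains a blacklisted token are always discarded.  Output preserves
    input order.
    """
    if discard_logic not in ("or", "and"):
        raise ValueError("discard_logic must be 'or' or 'and'")
    out: list[AlignmentHit] = []
    for h in hits:
        bad_e = h.evalue > max_evalue
        bad_i = h.percent_identity < min_identity
        discard = (bad_e or bad_i) if discard_logic == "or" else (bad_e and bad_i)
        if discard:
            continue
        if not _species_name_ok(h.subject_species, blacklist):
            continue
        out.append(h)
    return out


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


def to_seqrecords(db: ReferenceDatabase) -> list[SeqRecord]:
    return [SeqRecord(Seq(r.sequence), id=r.id,
                      description=r.lineage.to_string(db.dialect))
            for r in db.records]
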