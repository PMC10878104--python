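"""In-silico PCR over degenerate primer sets.

Each hypervariable-region primer set is matched against templates with an
IUPAC-aware mismatch count, a configurable per-primer mismatch allowance and
a 3′ clamp (terminal bases that must match exactly, because a 3′ mismatch
aborts polymerase extension).  Both template strands are scanned; each
forward site is paired with the nearest downstream reverse-complemented
reverse-primer site (shortest product), and the extracted amplicon is
primer-inclusive.

Coordinates are 0-based half-open on the plus strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_io import ReferenceDatabase, ReferenceRecord, reverse_complement

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_PRIMER_ALPHABET = frozenset(IUPAC)


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - _PRIMER_ALPHABET:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC sequence {seq!r}")
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r}: shorter than 10 nt")
        if self.weight <= 0:
            raise ValueError(f"primer {self.name!r}: non-positive weight")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    region: str
    forward: tuple[Primer, ...]
    reverse: Primer

    def __post_init__(self) -> None:
        if not self.forward:
            raise ValueError(f"primer set {self.region!r} has no forward primer")


FULL_LENGTH = "full-length"


def builtin_panel() -> dict[str, PrimerSet]:
    """The eight built-in primer sets (full-length plus seven region sets).

    The V1–V2 and V1–V3 sets use the 27F mixture with forward weights 4:1
    (27F-A : 27F-B); the weights are carried as sampling metadata for the
    read simulator and do not affect site detection, which takes the union
    over forward primers.
    """
    p = {
        "27F": Primer("27F", "AGRGTTYGATYMTGGCTCAG"),
        "1492R": Primer("1492R", "RGYTACCTTGTTACGACTT"),
        "27F-A": Primer("27F-A", "AGAGTTYGATYMTGGCTYAG", weight=4.0),
        "27F-B": Primer("27F-B", "AGARTTTGATCYTGGTTCAG", weight=1.0),
        "338R": Primer("338R", "TGCTGCCTCCCGTAGGAGT"),
        "533R": Primer("533R", "ATTACCGCGGCTGCTGG"),
        "338F": Primer("338F", "ACTCCTACGGGAGGCAGCAG"),
        "806R": Primer("806R", "GGACTACHVGGGTWTCTAAT"),
        "515F": Primer("515F", "GTGCCAGCMGCCGCGG"),
        "533F": Primer("533F", "GTGCCAGCMGCCGCGGTAA"),
        "1100R": Primer("1100R", "GGGTTGCGCTCGTTG"),
        "799F": Primer("799F", "AACMGGATTAGATACCCKG"),
        "1175R": Primer("1175R", "ACGTCRTCCCCDCCTTCCT"),
        "1115F": Primer("1115F", "YAACGAGCGCAACCC"),
        "1492R-vb": Primer("1492R", "CGGTTACCTTGTTACGACTT"),
    }
    mixture = (p["27F-A"], p["27F-B"])
    panel = {
        FULL_LENGTH: PrimerSet(FULL_LENGTH, (p["27F"],), p["1492R"]),
        "V1-V2": PrimerSet("V1-V2", mixture, p["338R"]),
        "V1-V3": PrimerSet("V1-V3", mixture, p["533R"]),
        "V3-V4": PrimerSet("V3-V4", (p["338F"],), p["806R"]),
        "V4": PrimerSet("V4", (p["515F"],), p["806R"]),
        "V4-V6": PrimerSet("V4-V6", (p["533F"],), p["1100R"]),
        "V5-V7": PrimerSet("V5-V7", (p["799F"],), p["1175R"]),
        "V7-V9": PrimerSet("V7-V9", (p["1115F"],), p["1492R-vb"]),
    }
    return panel


def load_panel_tsv(path: str | Path) -> dict[str, PrimerSet]:
    """Load user primer sets from a TSV: region, name, direction {F,R}, sequence, weight."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["region", "name", "direction", "sequence", "weight"],
                     header=None, dtype={"sequence": str})
    panel: dict[str, PrimerSet] = {}
    for region, grp in df.groupby("region", sort=False):
        fwd = tuple(Primer(r["name"], r.sequence, float(r.weight))
                    for r in grp.itertuples() if r.direction.upper() == "F")
        rev = [Primer(r["name"], r.sequence, float(r.weight))
               for r in grp.itertuples() if r.direction.upper() == "R"]
        if len(rev) != 1:
            raise ValueError(f"region {region!r}: exactly one reverse primer required")
        panel[str(region)] = PrimerSet(str(region), fwd, rev[0])
    return panel


def iupac_match(primer_window: str, template_window: str) -> int:
    """Count template positions outside the primer symbol's IUPAC expansion.

    A template ``N`` (or any non-ACGT base) matches nothing unless the primer
    symbol itself is ``N``.
    """
    if len(primer_window) != len(template_window):
        raise ValueError("primer and template windows differ in length")
    mm = 0
    for p, t in zip(primer_window.upper(), template_window.upper()):
        if p == "N":
            continue
        if t not in IUPAC.get(p, frozenset()):
            mm += 1
    return mm


@dataclass(frozen=True)
class _Site:
    start: int
    end: int
    mismatches: int
    primer_name: str


def _find_sites(template: str, primer: Primer, max_mismatch: int, clamp: int,
                as_reverse: bool) -> list[_Site]:
    """All primer-binding sites on the plus strand of ``template``.

    For a reverse primer the plus-strand window is reverse-complemented before
    comparison, so the clamp (the primer's 3′-terminal ``clamp`` bases) always
    refers to the end of the primer itself.
    """
    L, P = len(template), len(primer)
    if P > L:
        return []
    pseq = primer.sequence
    clamp = min(clamp, P)
    sites: list[_Site] = []
    for i in range(L - P + 1):
        window = template[i:i + P]
        if as_reverse:
            window = reverse_complement(window)
        mm_clamp = iupac_match(pseq[P - clamp:], window[P - clamp:]) if clamp else 0
        if mm_clamp:
            continue
        mm = mm_clamp + iupac_match(pseq[:P - clamp], window[:P - clamp])
        if mm <= max_mismatch:
            sites.append(_Site(i, i + P, mm, primer.name))
    return sites


@dataclass(frozen=True)
class Amplicon:
    source_id: str
    region: str
    start: int
    end: int
    strand: str
    fwd_mismatches: int
    rev_mismatches: int
    sequence: str
    fwd_primer: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def header(self) -> str:
        return (f"{self.source_id}|{self.region}|{self.start}-{self.end}|"
                f"{self.strand}|{self.fwd_mismatches},{self.rev_mismatches}")


def _amplify_plus(seq: str, pset: PrimerSet, max_mismatch: int, clamp: int,
                  min_length: int, max_length: int, all_products: bool
                  ) -> list[tuple[_Site, _Site]]:
    fwd_sites: dict[tuple[int, int], _Site] = {}
    for primer in pset.forward:
        for s in _find_sites(seq, primer, max_mismatch, clamp, as_reverse=False):
            key = (s.start, s.end)
            if key not in fwd_sites or s.mismatches < fwd_sites[key].mismatches:
                fwd_sites[key] = s
    if not fwd_sites:
        return []
    rev_sites = _find_sites(seq, pset.reverse, max_mismatch, clamp, as_reverse=True)
    if not rev_sites:
        return []
    rev_sites.sort(key=lambda s: s.start)
    pairs: list[tuple[_Site, _Site]] = []
    for f in sorted(fwd_sites.values(), key=lambda s: s.start):
        candidates = [r for r in rev_sites
                      if r.start >= f.end and min_length <= r.end - f.start <= max_length]
        if not candidates:
            continue
        if all_products:
            pairs.extend((f, r) for r in candidates)
        else:
            pairs.append((f, candidates[0]))  # nearest reverse site: shortest product
    return pairs


def amplify(record: ReferenceRecord | tuple[str, str], pset: PrimerSet,
            max_mismatch: int = 1, clamp: int = 4,
            min_length: int = 50, max_length: int = 5000,
            all_products: bool = False, strip_primers: bool = False
            ) -> list[Amplicon]:
    """Simulate PCR of one template with one primer set.

    Scans both strands; returns primer-inclusive amplicons sorted by plus-strand
    start (minus-strand products carry plus-strand coordinates and a
    reverse-complemented sequence).  No binding site → empty list.
    """
    if max_mismatch < 0 or clamp < 0:
        raise ValueError("max_mismatch and clamp must be non-negative")
    if isinstance(record, tuple):
        source_id, seq = record
    else:
        source_id, seq = record.id, record.sequence
    seq = seq.upper()
    out: list[Amplicon] = []
    for strand, template in (("+", seq), ("-", reverse_complement(seq))):
        for f, r in _amplify_plus(template, pset, max_mismatch, clamp,
                                  min_length, max_length, all_products):
            a, b = f.start, r.end
            prod = template[a:b]
            if strip_primers:
                prod = prod[f.end - f.start: len(prod) - (r.end - r.start)]
            if strand == "+":
                start, end = a, b
            else:
                start, end = len(seq) - b, len(seq) - a
            out.append(Amplicon(source_id, pset.region, start, end, strand,
                                f.mismatches, r.mismatches, prod, f.primer_name))
    out.sort(key=lambda x: (x.start, x.end, x.strand))
    return out


def amplify_database(db: ReferenceDatabase, pset: PrimerSet, **params
                     ) -> tuple[list[Amplicon], pd.DataFrame]:
    """Amplify every record; report per-species amplification counts.

    The report has one row per species (plus a row for records without a
    species label) with columns ``species, region, n_records, n_amplified``.
    """
    amplicons: list[Amplicon] = []
    stats: dict[str, list[int]] = {}
    for rec in db.records:
        sp = rec.lineage.normalized_species or "(no species)"
        n = stats.setdefault(sp, [0, 0])
        n[0] += 1
        hits = amplify(rec, pset, **params)
        if hits:
            n[1] += 1
            amplicons.extend(hits)
    report = pd.DataFrame(
        [(sp, pset.region, v[0], v[1]) for sp, v in sorted(stats.items())],
        columns=["species", "region", "n_records", "n_amplified"])
    return amplicons, report


def truncate_reads(seqs: Sequence[str] | Mapping[str, str], length_bp: int):
    """Truncate each sequence to its first ``length_bp`` bases (order kept).

    Emulates keeping only forward reads of a fixed sequencing length; shorter
    sequences pass through unchanged.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if isinstance(seqs, Mapping):
        return {k: v[:length_bp] for k, v in seqs.items()}
    return [s[:length_bp] for s in seqs]


def write_amplicon_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    """Amplicon FASTA with header ``sourceID|region|start-end|strand|mmF,mmR``
    (coordinates 0-based half-open on the plus strand)."""
    with open(path, "wt") as fh:
        for a in amplicons:
            fh.write(f">{a.header()}\n{a.sequence}\n")
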