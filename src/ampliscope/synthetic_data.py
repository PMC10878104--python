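"""Hermetic fixture generator: reference worlds and mock-community reads.

The generator builds ~1.5 kb species sequences with the block structure of a
16S rRNA gene: fixed conserved blocks carrying every built-in primer-binding
site at realistic spacings (V1–V3 span ≈ 500 bp, V4 ≈ 290 bp), alternating
with nine variable blocks that diverge per species from a shared backbone.
Where two primers physically overlap on the real gene (515F ⊂ 533F, the
338F/338R palindrome, 1100R/1115F, the two 1492R variants) the conserved
blocks overlap the same way, so each primer has exactly one binding site.

Three derived reference databases carry engineered, complementary defects —
one mislabels a species subset, one omits a subset, one truncates lineages
to genus for a subset — guaranteeing that no single database classifies all
species best, which is the condition the combination rule exploits.

Per-species *primer dropout* marks a region un-amplifiable by mutating bases
unique to that region's primer footprint.  For unshared sites the whole site
is scrambled; for shared sites a single 3′-clamp base of the target primer
is mutated, which leaves the co-located primer within the default mismatch
allowance (dropout semantics are therefore guaranteed under the default
matching parameters, max_mismatch = 1 with a 4-base clamp).  The universal
27F/1492R footprints strictly contain the region primers', so full-length
dropout is impossible and raises.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .insilico_pcr import FULL_LENGTH, amplify, builtin_panel
from .reference_io import (ReferenceDatabase, ReferenceRecord, TaxonomyLineage,
                           normalize_species, reverse_complement)

_BASES = np.array(list("ACGT"))


def _child_rng(seed: int, *labels: str) -> np.random.Generator:
    """A named, independently reproducible stream derived from one seed."""
    entropy = [int(seed)] + [zlib.crc32(l.encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            positions: np.ndarray | None = None) -> str:
    """Substitute bases iid at ``rate``, optionally only at ``positions``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    idx = positions if positions is not None else np.arange(len(arr))
    hit = idx[rng.random(len(idx)) < rate]
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Conserved-block layout (concrete resolutions of the degenerate primers)
# ---------------------------------------------------------------------------

_rc = reverse_complement

SITE_27F = "AGAGTTTGATCATGGCTCAG"            # exact for 27F and 27F-A
SITE_338FR = "ACTCCTACGGGAGGCAGCAG"          # 338F fwd; [0:19] is rc(338R)
SITE_533R = _rc("ATTACCGCGGCTGCTGG")         # CCAGCAGCCGCGGTAAT
SITE_515F_533F = "GTGCCAGCCGCCGCGGTAA"       # M→C; 515F = [0:16], 533F = all
SITE_799F = "AACAGGATTAGATACCCTG"            # M→A, K→T
SITE_806R = "ATTAGATACCCTGGTAGTCC"           # rc(806R) with W→T, B→T, D→G
SITE_1100R_1115F = "CAACGAGCGCAACCC"         # rc(1100R) == 1115F with Y→C
SITE_1175R = _rc("ACGTCATCCCCGCCTTCCT")      # R→A, D→G
SITE_1492 = _rc("CGGTTACCTTGTTACGACTT")      # [0:19] also binds full-length 1492R

#: (block-name, kind, fixed-string | variable-length)
_LAYOUT: tuple[tuple[str, str, object], ...] = (
    ("pad0", "cons", "GATCACTG"),
    ("27F", "site", SITE_27F),
    ("V1", "var", 122),
    ("sp1", "cons", "CGTAAGGTGA"),
    ("V2", "var", 150),
    ("338FR", "site", SITE_338FR),
    ("V3", "var", 140),
    ("sp3", "cons", "TTTGCA"),
    ("533R", "site", SITE_533R),
    ("sp4", "cons", "TTCA"),
    ("515F_533F", "site", SITE_515F_533F),
    ("sp5", "cons", "CCG"),
    ("V4", "var", 230),
    ("799F", "site", SITE_799F),
    ("sp6", "cons", "TTGTTG"),
    ("806R", "site", SITE_806R),
    ("V5", "var", 140),
    ("sp7", "cons", "AGGCTAAC"),
    ("V6", "var", 110),
    ("1100R_1115F", "site", SITE_1100R_1115F),
    ("V7", "var", 55),
    ("1175R", "site", SITE_1175R),
    ("V8", "var", 130),
    ("sp8", "cons", "GGTACTGC"),
    ("V9", "var", 150),
    ("1492R", "site", SITE_1492),
    ("pad1", "cons", "ACGGTCATCG"),
)

VARIABLE_BLOCKS: tuple[str, ...] = tuple(
    name for name, kind, _ in _LAYOUT if kind == "var")

#: how each region's primer footprint can be knocked out without touching the
#: other primers sharing its conserved blocks:
#:   ("scramble", block)      — replace the whole (unshared) site
#:   ("point", block, (i,..)) — mutate the listed in-block positions (a clamp
#:                               base of the target primer, tolerable by the
#:                               co-located primer at max_mismatch 1)
_DROPOUT_EDIT: dict[str, tuple] = {
    "V1-V2": ("point", "338FR", (1,)),          # 338R clamp ([0:4]); 338F tolerates
    "V1-V3": ("scramble", "533R"),
    "V3-V4": ("point", "338FR", (19,)),         # 338F clamp; outside 338R footprint
    "V4": ("point", "515F_533F", (13,)),        # 515F clamp; 533F tolerates
    "V4-V6": ("point", "515F_533F", (17, 18)),  # 533F clamp tail; outside 515F
    "V5-V7": ("scramble", "799F"),
    "V7-V9": ("point", "1100R_1115F", (12,)),   # 1115F clamp; 1100R tolerates
}


def block_layout() -> dict[str, tuple[int, int]]:
    """Plus-strand [start, end) coordinates of every block."""
    out: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, kind, spec in _LAYOUT:
        n = len(spec) if isinstance(spec, str) else int(spec)
        out[name] = (pos, pos + n)
        pos += n
    return out


BACKBONE_LENGTH = sum(len(s) if isinstance(s, str) else int(s)
                      for _, _, s in _LAYOUT)


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Recipe for one species' sequence."""

    name: str
    lineage: TaxonomyLineage
    divergence: float = 0.25            # substitutions/base in variable blocks
    sister_of: str | None = None        # copy shared blocks from this species
    shared_blocks: frozenset[str] = frozenset({"V3", "V4", "V5", "V6"})
    dropout_regions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MockCommunitySpec:
    """Recipe for one mock-community sample."""

    sample_id: str
    abundances: Mapping[str, float]
    n_reads: int
    error_rate: float = 0.0
    read_length: int | None = None      # None: full amplicon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")


_GENUS_TAXONOMY: dict[str, tuple[str, str, str, str]] = {
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Gardnerella": ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales",
                    "Bifidobacteriaceae"),
    "Bifidobacterium": ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales",
                        "Bifidobacteriaceae"),
    "Fannyhessea": ("Actinobacteriota", "Coriobacteriia", "Coriobacteriales",
                    "Atopobiaceae"),
    "Mobiluncus": ("Actinobacteriota", "Actinobacteria", "Actinomycetales",
                   "Actinomycetaceae"),
    "Prevotella": ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Megasphaera": ("Firmicutes", "Negativicutes", "Veillonellales",
                    "Veillonellaceae"),
    "Sneathia": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales",
                 "Leptotrichiaceae"),
    "Ureaplasma": ("Mycoplasmatota", "Mollicutes", "Mycoplasmatales",
                   "Mycoplasmataceae"),
}

DEFAULT_SPECIES: tuple[str, ...] = (
    "Lactobacillus crispatus", "Lactobacillus gasseri", "Lactobacillus iners",
    "Lactobacillus jensenii", "Gardnerella vaginalis", "Fannyhessea vaginae",
    "Prevotella bivia", "Megasphaera lornae", "Sneathia amnii",
    "Ureaplasma parvum", "Mobiluncus mulieris", "Bifidobacterium breve",
)

DATABASE_NAMES = ("greengenes2", "silva", "rdp")
_DB_DIALECT = {"greengenes2": "greengenes2", "silva": "silva", "rdp": "rdp"}


def lineage_for(species: str) -> TaxonomyLineage:
    genus = species.split()[0]
    phylum, cls, order, family = _GENUS_TAXONOMY.get(
        genus, ("SynthPhylum", "SynthClass", "SynthOrder", f"{genus}aceae"))
    return TaxonomyLineage(("Bacteria", phylum, cls, order, family, genus, species))


@dataclass
class ReferenceWorld:
    """A synthetic evaluation universe with known ground truth."""

    seed: int
    specs: list[SyntheticSpeciesSpec]
    truth_sequences: dict[str, str]
    databases: dict[str, ReferenceDatabase]
    manifest: dict

    @property
    def species(self) -> list[str]:
        return [s.name for s in self.specs]

    def truth_database(self, name: str = "truth") -> ReferenceDatabase:
        """A defect-free database holding every truth sequence once."""
        records = [ReferenceRecord(f"truth_{i:03d}", self.truth_sequences[s.name],
                                   s.lineage)
                   for i, s in enumerate(self.specs)]
        return ReferenceDatabase(name=name, records=records, dialect="qiime-generic")

    def amplicon_for(self, species: str, region: str, **params) -> str | None:
        """The species' (first) amplicon sequence for a region, or None."""
        pset = builtin_panel()[region]
        hits = amplify((species, self.truth_sequences[species]), pset, **params)
        return hits[0].sequence if hits else None

    def write(self, outdir: str | Path) -> None:
        from .reference_io import write_fasta
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truth = self.truth_database()
        write_fasta(truth, outdir / "truth.fasta")
        with open(outdir / "truth_lineages.tsv", "wt") as fh:
            for s in self.specs:
                fh.write(f"{s.name}\t{s.lineage.key()}\n")
        for name, db in self.databases.items():
            write_fasta(db, outdir / f"{name}.fasta")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str))


def _apply_dropout(seq: str, regions: Iterable[str],
                   rng: np.random.Generator) -> str:
    layout = block_layout()
    arr = np.array(list(seq))
    for region in sorted(regions):
        if region == FULL_LENGTH:
            raise ValueError(
                "full-length dropout is impossible: the universal primer "
                "footprints contain every region primer's")
        if region not in _DROPOUT_EDIT:
            raise ValueError(f"unknown region for dropout: {region!r}")
        edit = _DROPOUT_EDIT[region]
        if edit[0] == "scramble":
            a, b = layout[edit[1]]
            arr[a:b] = rng.choice(_BASES, size=b - a)
        else:
            a, _ = layout[edit[1]]
            for off in edit[2]:
                i = a + off
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def build_species_specs(n_species: int, n_sister_pairs: int,
                        dropout: Mapping[str, Iterable[str]] | None = None,
                        divergence: float = 0.25) -> list[SyntheticSpeciesSpec]:
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_sister_pairs * 2 > n_species:
        raise ValueError(f"{n_sister_pairs} sister pairs need "
                         f"{n_sister_pairs * 2} species, have {n_species}")
    names = list(DEFAULT_SPECIES[:n_species])
    for i in range(len(names), n_species):
        names.append(f"Synthetigena species{i - len(DEFAULT_SPECIES) + 1}")
    dropout = {normalize_species(k): frozenset(v)
               for k, v in (dropout or {}).items()}
    specs: list[SyntheticSpeciesSpec] = []
    for i, name in enumerate(names):
        # sister pairs occupy the front of the roster pairwise: (0,1), (2,3), ...
        sister = names[i - 1] if (i % 2 == 1 and i // 2 < n_sister_pairs) else None
        specs.append(SyntheticSpeciesSpec(
            name=name, lineage=lineage_for(name), divergence=divergence,
            sister_of=sister,
            dropout_regions=dropout.get(normalize_species(name), frozenset())))
    return specs


def make_reference_world(
    n_species: int = 12,
    n_sister_pairs: int = 2,
    seed: int = 0,
    n_records_per_species: int = 3,
    record_mutation_rate: float = 0.005,
    dropout: Mapping[str, Iterable[str]] | None = None,
    divergence: float = 0.25,
    defect_size: int | None = None,
) -> ReferenceWorld:
    """Build truth sequences plus three defective reference databases.

    Database defects (disjoint species subsets of size ``defect_size``,
    default ``max(1, n_species // 6)``): *greengenes2* swaps lineages within
    its subset (mislabels), *silva* omits its subset, *rdp* truncates its
    subset's lineages at genus.  Record-level mutations are confined to
    variable blocks so amplification is never lost by sampling noise.
    """
    specs = build_species_specs(n_species, n_sister_pairs, dropout, divergence)
    layout = block_layout()

    backbone_rng = _child_rng(seed, "backbone")
    backbone_blocks = {name: _random_dna(backbone_rng, int(spec))
                       for name, kind, spec in _LAYOUT if kind == "var"}

    species_rng = _child_rng(seed, "species")
    blocks_by_species: dict[str, dict[str, str]] = {}
    truth: dict[str, str] = {}
    for sp in specs:
        blocks: dict[str, str] = {}
        for name in VARIABLE_BLOCKS:
            if sp.sister_of is not None and name in sp.shared_blocks:
                blocks[name] = blocks_by_species[sp.sister_of][name]
            else:
                blocks[name] = _mutate(backbone_blocks[name], sp.divergence,
                                       species_rng)
        blocks_by_species[sp.name] = blocks
        parts = []
        for name, kind, spec in _LAYOUT:
            parts.append(spec if kind != "var" else blocks[name])
        seq = "".join(parts)
        if sp.dropout_regions:
            seq = _apply_dropout(seq, sp.dropout_regions,
                                 _child_rng(seed, "dropout", sp.name))
        truth[sp.name] = seq

    var_positions = np.concatenate([np.arange(*layout[b]) for b in VARIABLE_BLOCKS])

    if defect_size is None:
        defect_size = max(1, n_species // 6)
    pick_rng = _child_rng(seed, "defects")
    shuffled = [str(x) for x in pick_rng.permutation([s.name for s in specs])]
    mislabeled = shuffled[:max(2, defect_size)]
    omitted = shuffled[len(mislabeled):len(mislabeled) + defect_size]
    truncated = shuffled[len(mislabeled) + defect_size:
                         len(mislabeled) + 2 * defect_size]

    # mislabeling = rotate lineages within the subset
    relabel = {a: lineage_for(b)
               for a, b in zip(mislabeled, mislabeled[1:] + mislabeled[:1])}

    databases: dict[str, ReferenceDatabase] = {}
    for db_name in DATABASE_NAMES:
        rec_rng = _child_rng(seed, "records", db_name)
        records: list[ReferenceRecord] = []
        for i, sp in enumerate(specs):
            if db_name == "silva" and sp.name in omitted:
                continue
            lineage = sp.lineage
            if db_name == "greengenes2" and sp.name in relabel:
                lineage = relabel[sp.name]
            if db_name == "rdp" and sp.name in truncated:
                lineage = lineage.truncate(6)
            for j in range(n_records_per_species):
                seq = _mutate(truth[sp.name], record_mutation_rate, rec_rng,
                              positions=var_positions)
                records.append(ReferenceRecord(f"{db_name}_{i:03d}_{j}", seq,
                                               lineage))
        databases[db_name] = ReferenceDatabase(
            name=db_name, records=records, dialect=_DB_DIALECT[db_name])

    manifest = {
        "seed": seed, "n_species": n_species, "n_sister_pairs": n_sister_pairs,
        "n_records_per_species": n_records_per_species,
        "record_mutation_rate": record_mutation_rate,
        "divergence": divergence, "backbone_length": BACKBONE_LENGTH,
        "species": [s.name for s in specs],
        "sister_pairs": [[s.sister_of, s.name] for s in specs if s.sister_of],
        "dropout": {s.name: sorted(s.dropout_regions)
                    for s in specs if s.dropout_regions},
        "defects": {"greengenes2_mislabeled": sorted(mislabeled),
                    "silva_omitted": sorted(omitted),
                    "rdp_truncated": sorted(truncated)},
    }
    return ReferenceWorld(seed=seed, specs=specs, truth_sequences=truth,
                          databases=databases, manifest=manifest)


# ---------------------------------------------------------------------------
# Mock-community read simulation
# ---------------------------------------------------------------------------

def simulate_reads(world: ReferenceWorld, mock: MockCommunitySpec, region: str
                   ) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw reads multinomially from a mock composition for one region.

    Each read is the species' amplicon for the region (the forward primer of
    a mixture is sampled by its 4:1 weights and recorded), mutated iid at the
    spec's error rate and truncated to the read length.  Species whose region
    is un-amplifiable get zero reads (primer dropout) with a warning; the
    remaining species absorb the read budget.  Deterministic given the spec
    seed.
    """
    panel = builtin_panel()
    if region not in panel:
        raise ValueError(f"unknown region {region!r}")
    pset = panel[region]
    rng = _child_rng(mock.seed, "reads", mock.sample_id, region)

    amplicons: dict[str, str] = {}
    probs: list[float] = []
    names: list[str] = []
    for sp, ab in sorted(mock.abundances.items()):
        if ab <= 0:
            continue
        if sp not in world.truth_sequences:
            raise KeyError(f"species {sp!r} not in world")
        amp = world.amplicon_for(sp, region)
        if amp is None:
            warnings.warn(f"{sp!r} is un-amplifiable for {region}; zero reads",
                          stacklevel=2)
            continue
        amplicons[sp] = amp
        names.append(sp)
        probs.append(ab)
    if not names:
        raise ValueError(f"no amplifiable species for region {region}")
    p = np.array(probs) / sum(probs)
    counts = rng.multinomial(mock.n_reads, p)

    fwd_names = [pr.name for pr in pset.forward]
    fwd_w = np.array([pr.weight for pr in pset.forward], dtype=float)
    fwd_w /= fwd_w.sum()

    reads: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []
    i = 0
    for sp, n in zip(names, counts):
        for _ in range(n):
            rid = f"{mock.sample_id}_r{i:06d}"
            i += 1
            seq = _mutate(amplicons[sp], mock.error_rate, rng)
            if mock.read_length is not None:
                seq = seq[:mock.read_length]
            fwd = fwd_names[rng.choice(len(fwd_names), p=fwd_w)] \
                if len(fwd_names) > 1 else fwd_names[0]
            reads[rid] = seq
            rows.append((rid, sp, fwd))
    table = pd.DataFrame(rows, columns=["read_id", "species", "fwd_primer"])
    return reads, table


def write_fastq(reads: Mapping[str, str], path: str | Path,
                quality_char: str = "I") -> None:
    with open(path, "wt") as fh:
        for rid, seq in reads.items():
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
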