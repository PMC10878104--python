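"""In-silico PCR: primer panel, IUPAC matching, and oracle equivalence.

The independent oracle expands every degenerate primer into its full set of
concrete strings and finds binding sites by overlapped regex search; amplify
at max-mismatch 0 must agree exactly on coordinates, counts and sequences.
"""

import itertools
import re

import numpy as np
import pytest

from ampliscope.insilico_pcr import (IUPAC, Amplicon, Primer, PrimerSet,
                                     amplify, amplify_database, builtin_panel,
                                     iupac_match, truncate_reads)
from ampliscope.reference_io import (ReferenceDatabase, ReferenceRecord,
                                     reverse_complement)

# ---------------------------------------------------------------------------
# Independent oracle: IUPAC expansion + regex search
# ---------------------------------------------------------------------------

def _expand(primer_seq: str) -> list[str]:
    return ["".join(t) for t in
            itertools.product(*(sorted(IUPAC[c]) for c in primer_seq))]


def _regex_sites(template: str, primer_seq: str, as_reverse: bool) -> list[tuple[int, int]]:
    """All 0-mismatch plus-strand sites via regex over the expansion."""
    target = reverse_complement(primer_seq) if as_reverse else primer_seq
    pattern = "(?=(" + "|".join(re.escape(s) for s in _expand(target)) + "))"
    n = len(primer_seq)
    return [(m.start(), m.start() + n)
            for m in re.finditer(pattern, template)]


def oracle_amplify(source_id: str, seq: str, pset: PrimerSet,
                   min_length: int = 50, max_length: int = 5000) -> list[Amplicon]:
    """Brute-force exact-match amplification (nearest-reverse pairing)."""
    out = []
    L = len(seq)
    for strand, template in (("+", seq), ("-", reverse_complement(seq))):
        fwd = sorted(set(s for p in pset.forward
                         for s in _regex_sites(template, p.sequence, False)))
        rev = sorted(_regex_sites(template, pset.reverse.sequence, True))
        for (fa, fb) in fwd:
            cands = [(ra, rb) for (ra, rb) in rev
                     if ra >= fb and min_length <= rb - fa <= max_length]
            if not cands:
                continue
            ra, rb = cands[0]
            if strand == "+":
                start, end = fa, rb
            else:
                start, end = L - rb, L - fa
            out.append(Amplicon(source_id, pset.region, start, end, strand,
                                0, 0, template[fa:rb]))
    out.sort(key=lambda a: (a.start, a.end, a.strand))
    return out


def _strip_names(amps):
    return [(a.start, a.end, a.strand, a.sequence) for a in amps]


def _planted_template(rng: np.random.Generator, pset: PrimerSet,
                      length: int = 2000) -> str:
    """Random template with 0–3 planted concrete primer sites per direction."""
    bases = np.array(list("ACGT"))
    arr = rng.choice(bases, size=length)
    for _ in range(rng.integers(0, 4)):
        primer = pset.forward[rng.integers(len(pset.forward))]
        site = "".join(rng.choice(sorted(IUPAC[c])) for c in primer.sequence)
        pos = rng.integers(0, length - len(site))
        arr[pos:pos + len(site)] = list(site)
    for _ in range(rng.integers(0, 4)):
        site = reverse_complement(
            "".join(rng.choice(sorted(IUPAC[c])) for c in pset.reverse.sequence))
        pos = rng.integers(0, length - len(site))
        arr[pos:pos + len(site)] = list(site)
    return "".join(arr)


# ---------------------------------------------------------------------------
# Built-in panel
# ---------------------------------------------------------------------------

class TestBuiltinPanel:
    def test_panel_has_eight_primer_sets(self, panel):
        assert len(panel) == 8
        assert set(panel) == {"full-length", "V1-V2", "V1-V3", "V3-V4", "V4",
                              "V4-V6", "V5-V7", "V7-V9"}

    def test_v4_primer_sequences(self, panel):
        assert panel["V4"].forward[0].sequence == "GTGCCAGCMGCCGCGG"
        assert panel["V4"].reverse.sequence == "GGACTACHVGGGTWTCTAAT"

    @pytest.mark.parametrize("region", ["V1-V2", "V1-V3"])
    def test_27f_mixture_weights_4_to_1(self, panel, region):
        fwd = panel[region].forward
        assert [p.name for p in fwd] == ["27F-A", "27F-B"]
        assert [p.weight for p in fwd] == [4.0, 1.0]

    def test_single_forward_elsewhere(self, panel):
        for region in ("full-length", "V3-V4", "V4", "V4-V6", "V5-V7", "V7-V9"):
            assert len(panel[region].forward) == 1

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            Primer("bad", "ACGTXACGTT")
        with pytest.raises(ValueError):
            Primer("short", "ACGTACGT")


class TestIupacMatch:
    @pytest.mark.parametrize("primer,template,expected", [
        ("GTGCCAGCMGCCGCGG", "GTGCCAGCAGCCGCGG", 0),   # M = A/C
        ("GTGCCAGCMGCCGCGG", "GTGCCAGCTGCCGCGG", 1),   # T not in M
        ("ACGTACGTAC", "ACGTACGTAC", 0),
        ("NNNNNNNNNN", "ACGTACGTNN", 0),               # primer N matches all
        ("ACGTACGTAC", "NCGTACGTAC", 1),               # template N matches nothing
    ])
    def test_mismatch_counting(self, primer, template, expected):
        assert iupac_match(primer, template) == expected

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            iupac_match("ACGT", "ACGTA")


# ---------------------------------------------------------------------------
# amplify
# ---------------------------------------------------------------------------

def _v4_template(fwd_site=None, rev_site=None, insert=100, pad=30):
    fwd_site = fwd_site or "GTGCCAGCAGCCGCGG"
    rev_site = rev_site or reverse_complement("GGACTACTAGGGTATCTAAT")
    rng = np.random.default_rng(0)
    mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return mk(pad) + fwd_site + mk(insert) + rev_site + mk(pad)


class TestAmplify:
    def test_constructed_template_single_product(self, panel):
        t = _v4_template()
        amps = amplify(("t", t), panel["V4"], max_mismatch=0)
        assert len(amps) == 1
        a = amps[0]
        assert (a.start, a.end, len(a)) == (30, 166, 136)
        assert a.sequence == t[30:166]
        assert a.strand == "+" and a.fwd_mismatches == 0

    def test_mismatch_allowance_and_counting(self, panel):
        t = _v4_template()
        mutated = t[:33] + ("C" if t[33] != "C" else "G") + t[34:]
        assert amplify(("t", mutated), panel["V4"], max_mismatch=0) == []
        amps = amplify(("t", mutated), panel["V4"], max_mismatch=1)
        assert len(amps) == 1 and amps[0].fwd_mismatches == 1

    def test_three_prime_clamp_rejects_terminal_mismatch(self, panel):
        t = _v4_template()
        # last base of the forward site (position 45) is within the clamp
        mutated = t[:45] + ("A" if t[45] != "A" else "T") + t[46:]
        assert amplify(("t", mutated), panel["V4"], max_mismatch=2, clamp=4) == []
        assert len(amplify(("t", mutated), panel["V4"], max_mismatch=2,
                           clamp=0)) == 1

    def test_no_reverse_site_gives_empty(self, panel):
        rng = np.random.default_rng(1)
        t = "".join(rng.choice(list("ACGT"), size=30)) + "GTGCCAGCAGCCGCGG" + \
            "".join(rng.choice(list("ACGT"), size=100))
        assert amplify(("t", t), panel["V4"]) == []

    def test_strand_symmetry(self, panel, world):
        seq = world.truth_sequences["Prevotella bivia"]
        fwd = amplify(("t", seq), panel["V4"])
        rev = amplify(("t", reverse_complement(seq)), panel["V4"])
        assert sorted(a.sequence for a in fwd) == sorted(a.sequence for a in rev)
        assert {a.strand for a in fwd} == {"+"} and {a.strand for a in rev} == {"-"}

    def test_minus_strand_coordinates_slice_the_source(self, panel, world):
        seq = reverse_complement(world.truth_sequences["Sneathia amnii"])
        for a in amplify(("t", seq), panel["V1-V3"]):
            assert a.strand == "-"
            assert a.sequence == reverse_complement(seq[a.start:a.end])

    def test_monotone_in_mismatch_allowance(self, panel):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = _planted_template(rng, panel["V4"])
            prev: set = set()
            for mm in (0, 1, 2):
                cur = {(a.start, a.end, a.strand)
                       for a in amplify(("t", t), panel["V4"],
                                        max_mismatch=mm, clamp=0)}
                assert prev <= cur
                prev = cur

    def test_oracle_equivalence_on_planted_templates(self, panel):
        rng = np.random.default_rng(11)
        pset = panel["V4"]
        for _ in range(50):
            t = _planted_template(rng, pset)
            got = amplify(("t", t), pset, max_mismatch=0, clamp=0)
            expected = oracle_amplify("t", t, pset)
            assert _strip_names(got) == _strip_names(expected)

    def test_all_products_supersets_nearest_pairing(self, panel):
        rng = np.random.default_rng(3)
        t = _planted_template(rng, panel["V4"])
        near = amplify(("t", t), panel["V4"], max_mismatch=0)
        allp = amplify(("t", t), panel["V4"], max_mismatch=0, all_products=True)
        assert set(_strip_names(near)) <= set(_strip_names(allp))

    def test_strip_primers_removes_both_sites(self, panel):
        t = _v4_template()
        (full,) = amplify(("t", t), panel["V4"], max_mismatch=0)
        (inner,) = amplify(("t", t), panel["V4"], max_mismatch=0,
                           strip_primers=True)
        assert len(inner) == len(full) - 16 - 20
        assert inner.sequence in full.sequence


class TestAmplifyDatabase:
    def test_dropout_species_report_zero(self, panel):
        from ampliscope.synthetic_data import make_reference_world
        w = make_reference_world(
            seed=5, dropout={"Lactobacillus iners": ["V1-V3"],
                             "Prevotella bivia": ["V1-V3"]})
        amps, report = amplify_database(w.truth_database(), panel["V1-V3"])
        zero = set(report.loc[report.n_amplified == 0, "species"])
        assert zero == {"Lactobacillus iners", "Prevotella bivia"}
        assert len(amps) == 10

    def test_full_length_one_amplicon_per_record(self, panel, world):
        amps, report = amplify_database(world.truth_database(),
                                        panel["full-length"])
        assert len(amps) == 12
        assert (report.n_amplified == report.n_records).all()

    def test_empty_database_empty_outputs(self, panel):
        db = ReferenceDatabase("empty", [], dialect="none")
        amps, report = amplify_database(db, panel["V4"])
        assert amps == [] and len(report) == 0


class TestTruncateReads:
    def test_forward_read_truncation(self):
        seqs = ["A" * 450, "C" * 150]
        out = truncate_reads(seqs, 223)
        assert [len(s) for s in out] == [223, 150]

    def test_idempotent(self):
        seqs = {"r1": "ACGT" * 100}
        once = truncate_reads(seqs, 223)
        assert truncate_reads(once, 223) == once

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            truncate_reads(["ACGT"], 0)
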