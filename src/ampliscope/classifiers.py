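"""Taxonomic classifiers: k-mer multinomial naive Bayes and top-hit consensus.

Two classifier families mirror the standard amplicon toolchain:

* :func:`train_nb` / :func:`classify_nb` — a multinomial naive Bayes over
  overlapping k-mer counts with Laplace smoothing, one class per distinct
  training lineage, and RDP-style bootstrap confidence (re-classify random
  k-mer subsamples; per-rank confidence is the fraction of subsamples whose
  winning class agrees at that rank).
* :class:`TopHitClassifier` / :func:`classify_tophit` — global pairwise
  alignment of the query against k-mer-prefiltered candidates; the predicted
  lineage is the deepest rank on which at least a threshold fraction of the
  accepted hits agree.

Both are deterministic: ties are broken lexicographically on the full
lineage string, and all randomness flows through an explicit seed.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .reference_io import (RANKS, ReferenceDatabase, TaxonomyLineage,
                           normalize_species, reverse_complement)

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

SPECIES_DEPTH = RANKS.index("species")


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Codes of all overlapping k-mers; windows containing non-ACGT are dropped."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        valid &= c >= 0
        out = out * 4 + np.where(c >= 0, c, 0)
    return out[valid]


@dataclass
class KmerModel:
    """Trained naive Bayes model: per-class log-probabilities over 4^k k-mers."""

    k: int
    alpha: float
    classes: list[str]                      # sorted canonical lineage keys
    log_prob: np.ndarray                    # (n_classes, 4**k)
    database: str = ""
    vocab_seen: np.ndarray = field(default=None)  # bool (4**k,), any training count > 0

    @property
    def lineages(self) -> list[TaxonomyLineage]:
        return [TaxonomyLineage.from_key(c) for c in self.classes]

    def save(self, path: str | Path) -> None:
        """Single-archive persistence: JSON metadata + binary matrices."""
        path = Path(path)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            meta = {"k": self.k, "alpha": self.alpha, "classes": self.classes,
                    "database": self.database}
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("log_prob.npy", self.log_prob.astype(np.float64).tobytes())
            zf.writestr("vocab_seen.npy", self.vocab_seen.astype(np.uint8).tobytes())

    @staticmethod
    def load(path: str | Path) -> "KmerModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            v = 4 ** meta["k"]
            lp = np.frombuffer(zf.read("log_prob.npy"), dtype=np.float64)
            lp = lp.reshape(len(meta["classes"]), v).copy()
            seen = np.frombuffer(zf.read("vocab_seen.npy"), dtype=np.uint8)
        return KmerModel(k=meta["k"], alpha=meta["alpha"], classes=meta["classes"],
                         log_prob=lp, database=meta["database"],
                         vocab_seen=seen.astype(bool).copy())


def train_nb(db: ReferenceDatabase | Sequence[tuple[str, TaxonomyLineage]],
             k: int = 8, alpha: float = 0.001) -> KmerModel:
    """Train the naive Bayes model, one class per distinct full lineage.

    Counts come from overlapping plus-strand k-mers of each training sequence
    (queries are orientation-normalized at classification time instead), then
    Laplace-smoothed with ``alpha``.
    """
    if not 4 <= k <= 12:
        raise ValueError("k must be in [4, 12]")
    if isinstance(db, ReferenceDatabase):
        items = [(r.sequence, r.lineage) for r in db.records]
        name = db.name
    else:
        items = list(db)
        name = ""
    if not items:
        raise ValueError("cannot train on an empty database")
    if all(len(seq) < k for seq, _ in items):
        raise ValueError(f"k={k} exceeds every training sequence length")

    classes = sorted({lin.key() for _, lin in items})
    index = {c: i for i, c in enumerate(classes)}
    v = 4 ** k
    counts = np.zeros((len(classes), v), dtype=np.float64)
    for seq, lin in items:
        codes = _kmer_codes(seq, k)
        if codes.size:
            counts[index[lin.key()]] += np.bincount(codes, minlength=v)
    row = counts.sum(axis=1, keepdims=True)
    log_prob = np.log(counts + alpha) - np.log(row + alpha * v)
    return KmerModel(k=k, alpha=alpha, classes=classes, log_prob=log_prob,
                     database=name, vocab_seen=counts.sum(axis=0) > 0)


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    lineage: TaxonomyLineage
    confidence: float
    method: str                 # "nb" | "tophit"
    database: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.confidence}")

    @property
    def species(self) -> str:
        return self.lineage.normalized_species


def _orient(seq: str, model: KmerModel) -> str:
    """Return the query orientation sharing more distinct k-mers with the model."""
    fwd = _kmer_codes(seq, model.k)
    rc = reverse_complement(seq)
    rev = _kmer_codes(rc, model.k)
    n_f = int(model.vocab_seen[np.unique(fwd)].sum()) if fwd.size else 0
    n_r = int(model.vocab_seen[np.unique(rev)].sum()) if rev.size else 0
    return rc if n_r > n_f else seq


def nb_log_posterior(model: KmerModel, seq: str) -> np.ndarray:
    """Per-class log joint (uniform prior omitted) for one plus-strand query."""
    codes = _kmer_codes(seq, model.k)
    if codes.size == 0:
        return np.zeros(len(model.classes))
    uniq, cnt = np.unique(codes, return_counts=True)
    return model.log_prob[:, uniq] @ cnt.astype(np.float64)


def _truncate_by_confidence(lineage: TaxonomyLineage, rank_conf: np.ndarray,
                            threshold: float) -> tuple[TaxonomyLineage, float]:
    depth = 0
    for i in range(len(lineage)):
        if rank_conf[i] >= threshold:
            depth = i + 1
        else:
            break
    conf = float(rank_conf[depth - 1]) if depth else float(rank_conf[0]) if len(lineage) else 0.0
    return lineage.truncate(depth), conf


def classify_nb(model: KmerModel, query: str, query_id: str = "query",
                confidence_threshold: float = 0.7, n_bootstrap: int = 100,
                subsample_fraction: float = 0.125, seed: int = 0,
                orient: bool = True) -> ClassificationResult:
    """Classify one query with bootstrap confidence.

    The point prediction is the argmax-posterior class over the query's k-mer
    multiset; per-rank confidence is the fraction of ``n_bootstrap`` random
    k-mer subsamples (size = fraction × k-mer count, drawn with replacement)
    whose winner agrees with the point prediction through that rank.  The
    lineage is truncated below the first rank failing the threshold.
    ``n_bootstrap=0`` skips the bootstrap and reports the full lineage with
    confidence 1.  Queries shorter than k are returned unclassified.
    """
    if len(query) < model.k:
        return ClassificationResult(query_id, TaxonomyLineage(), 0.0, "nb",
                                    model.database, flags=("too-short",))
    seq = _orient(query, model) if orient else query
    codes = _kmer_codes(seq, model.k)
    if codes.size == 0:
        return ClassificationResult(query_id, TaxonomyLineage(), 0.0, "nb",
                                    model.database, flags=("no-kmers",))
    uniq, cnt = np.unique(codes, return_counts=True)
    lp = model.log_prob[:, uniq]
    best = int(np.argmax(lp @ cnt.astype(np.float64)))   # first index = lexicographic tie-break
    lineage = TaxonomyLineage.from_key(model.classes[best])

    if n_bootstrap <= 0:
        return ClassificationResult(query_id, lineage, 1.0, "nb", model.database)

    rng = np.random.default_rng(seed)
    total = int(cnt.sum())
    m = max(1, int(round(total * subsample_fraction)))
    draws = rng.multinomial(m, cnt / total, size=n_bootstrap).astype(np.float64)
    winners = np.argmax(draws @ lp.T, axis=1)

    lineages = model.lineages
    rank_conf = np.zeros(len(RANKS))
    for w, n_w in zip(*np.unique(winners, return_counts=True)):
        wl = lineages[int(w)]
        for r in range(len(lineage)):
            if wl.agrees_at(lineage, r):
                rank_conf[r] += n_w
            else:
                break
    rank_conf /= n_bootstrap
    trunc, conf = _truncate_by_confidence(lineage, rank_conf, confidence_threshold)
    return ClassificationResult(query_id, trunc, conf, "nb", model.database)


def classify_nb_many(model: KmerModel, queries: dict[str, str], **kwargs
                     ) -> list[ClassificationResult]:
    """Classify a batch of queries; the per-query seed is derived from the
    batch seed and the query index so results do not depend on batch splits."""
    seed = int(kwargs.pop("seed", 0))
    out = []
    for i, (qid, seq) in enumerate(queries.items()):
        out.append(classify_nb(model, seq, query_id=qid,
                               seed=(seed + 9973 * i) % (2 ** 31), **kwargs))
    return out


# ---------------------------------------------------------------------------
# Top-hit consensus classifier
# ---------------------------------------------------------------------------

class TopHitClassifier:
    """Nearest-reference classifier by global pairwise alignment.

    Candidates are ranked by shared distinct k-mers (both query orientations
    tried), the best ``n_candidates`` are aligned globally (match +1,
    mismatch −1, gap open −5, gap extend −2), hits with identity ≥
    ``min_identity`` are kept up to ``max_accepts``, and the lineage is the
    rank-wise majority at ≥ ``consensus_threshold`` among kept hits.
    Confidence is the species-rank consensus fraction.
    """

    def __init__(self, db: ReferenceDatabase, k: int = 8, n_candidates: int = 16):
        if not len(db):
            raise ValueError("empty reference database")
        self.db = db
        self.k = k
        self.n_candidates = n_candidates
        # stable reference order: lexicographic on (lineage, id) for tie determinism
        self._refs = sorted(db.records, key=lambda r: (r.lineage.key(), r.id))
        self._kmer_sets = [frozenset(np.unique(_kmer_codes(r.sequence, k)).tolist())
                           for r in self._refs]
        self._aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                              mismatch_score=-1,
                                              open_gap_score=-5,
                                              extend_gap_score=-2)

    def _identity(self, query: str, ref: str) -> float:
        aln = self._aligner.align(query, ref)[0]
        c = aln.counts()
        total = c.identities + c.mismatches + c.gaps
        return c.identities / total if total else 0.0

    def classify(self, query: str, query_id: str = "query",
                 min_identity: float = 0.97, max_accepts: int = 10,
                 consensus_threshold: float = 0.51) -> ClassificationResult:
        qk_f = frozenset(np.unique(_kmer_codes(query, self.k)).tolist())
        qk_r = frozenset(np.unique(_kmer_codes(reverse_complement(query), self.k)).tolist())
        shared_f = [len(qk_f & s) for s in self._kmer_sets]
        shared_r = [len(qk_r & s) for s in self._kmer_sets]
        q = query if sum(shared_f) >= sum(shared_r) else reverse_complement(query)
        shared = shared_f if sum(shared_f) >= sum(shared_r) else shared_r
        order = sorted(range(len(self._refs)), key=lambda i: (-shared[i], i))
        cand = [i for i in order[:self.n_candidates] if shared[i] > 0] or order[:self.n_candidates]

        hits: list[tuple[float, int]] = []
        for i in cand:
            ident = self._identity(q, self._refs[i].sequence)
            if ident >= min_identity:
                hits.append((ident, i))
        hits.sort(key=lambda t: (-t[0], self._refs[t[1]].lineage.key()))
        hits = hits[:max_accepts]
        if not hits:
            return ClassificationResult(query_id, TaxonomyLineage(), 0.0,
                                        "tophit", self.db.name, flags=("no-hit",))

        kept = [self._refs[i].lineage for _, i in hits]
        n = len(kept)
        taxa: list[str] = []
        for depth in range(len(RANKS)):
            votes: dict[str, int] = {}
            for lin in kept:
                t = lin.taxa[depth] if len(lin) > depth else None
                if t is None:
                    continue
                key = normalize_species(t).lower() if depth == SPECIES_DEPTH else t
                # only count hits consistent with the consensus chosen so far
                if lin.taxa[:depth] == tuple(taxa):
                    votes[key] = votes.get(key, 0) + 1
            if not votes:
                break
            top = min((k for k, v in votes.items() if v == max(votes.values())))
            if votes[top] / n >= consensus_threshold:
                # recover a representative original spelling
                rep = next(lin.taxa[depth] for lin in kept
                           if len(lin) > depth and lin.taxa[:depth] == tuple(taxa)
                           and ((normalize_species(lin.taxa[depth]).lower()
                                 if depth == SPECIES_DEPTH else lin.taxa[depth]) == top))
                taxa.append(rep)
            else:
                break

        sp_votes: dict[str, int] = {}
        for lin in kept:
            if len(lin) > SPECIES_DEPTH:
                key = normalize_species(lin.taxa[SPECIES_DEPTH]).lower()
                sp_votes[key] = sp_votes.get(key, 0) + 1
        conf = max(sp_votes.values()) / n if sp_votes else 0.0
        return ClassificationResult(query_id, TaxonomyLineage(tuple(taxa)),
                                    conf, "tophit", self.db.name)


def classify_tophit(db: ReferenceDatabase, query: str, query_id: str = "query",
                    min_identity: float = 0.97, max_accepts: int = 10,
                    consensus_threshold: float = 0.51) -> ClassificationResult:
    """One-shot convenience wrapper around :class:`TopHitClassifier`."""
    return TopHitClassifier(db).classify(query, query_id, min_identity,
                                         max_accepts, consensus_threshold)


def write_classifications_tsv(results: Sequence[ClassificationResult],
                              path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("query_id\tlineage\tconfidence\tmethod\tdatabase\tflags\n")
        for r in results:
            fh.write(f"{r.query_id}\t{r.lineage.key()}\t{r.confidence:.4f}\t"
                     f"{r.method}\t{r.database}\t{','.join(r.flags)}\n")
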