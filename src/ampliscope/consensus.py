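"""Per-species accuracy scoring and the multi-database combination rule.

No single reference database classifies every species best: each has its own
coverage gaps, label errors and truncated lineages.  The combination rule
scores per-species accuracy for every (region, method, database) pipeline,
maps each species to the database that classifies it most accurately, and at
inference time accepts a database's species call only when that database is
the designated authority for the species it called.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassificationResult
from .reference_io import TaxonomyLineage, normalize_species

#: the clinically pivotal vaginal species every pipeline must separate
KEY_LACTOBACILLUS: frozenset[str] = frozenset({
    "Lactobacillus crispatus", "Lactobacillus gasseri",
    "Lactobacillus iners", "Lactobacillus jensenii",
})


def _spkey(name: str) -> str:
    return normalize_species(name).lower()


@dataclass
class AccuracyEntry:
    n_correct: int = 0
    n_total: int = 0

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total if self.n_total else 0.0


@dataclass
class AccuracyTable:
    """Per-(species, region, method, database) accuracy grid.

    Species keys are normalized lower-case binomials; ``display`` maps them
    back to a printable spelling.  Subsets tag groups of species (the
    key-Lactobacillus quartet is built in) for subgroup summaries.
    """

    entries: dict[tuple[str, str, str, str], AccuracyEntry] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)
    subsets: dict[str, frozenset[str]] = field(
        default_factory=lambda: {"key_lactobacillus":
                                 frozenset(_spkey(s) for s in KEY_LACTOBACILLUS)})

    def add(self, species: str, region: str, method: str, database: str,
            correct: bool) -> None:
        key = (_spkey(species), region, method, database)
        e = self.entries.setdefault(key, AccuracyEntry())
        e.n_total += 1
        e.n_correct += int(correct)
        self.display.setdefault(_spkey(species), normalize_species(species))

    def accuracy(self, species: str, region: str, method: str, database: str) -> float:
        e = self.entries.get((_spkey(species), region, method, database))
        return e.accuracy if e else 0.0

    def species_for(self, region: str, method: str,
                    database: str | None = None) -> list[str]:
        return sorted({sp for (sp, rg, me, db) in self.entries
                       if rg == region and me == method
                       and (database is None or db == database)})

    def databases_for(self, region: str, method: str) -> list[str]:
        return sorted({db for (_, rg, me, db) in self.entries
                       if rg == region and me == method})

    def pipeline_summary(self, region: str, method: str, database: str,
                         subset: str | None = None) -> tuple[float, float, int]:
        """Unweighted mean ± sd of per-species accuracy across species.

        Species missing from this pipeline's predictions count as accuracy 0
        (the pipeline failed to classify them at all).  Returns
        (mean, sd, n_species); sd is the sample sd (0 when n == 1).
        """
        species = self.species_for(region, method)
        if subset is not None:
            members = self.subsets[subset]
            species = [s for s in species if s in members]
        if not species:
            raise ValueError(f"no species scored for ({region}, {method})"
                             + (f" subset {subset}" if subset else ""))
        acc = np.array([self.accuracy(s, region, method, database) for s in species])
        sd = float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0
        return float(np.mean(acc)), sd, len(species)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.display.get(sp, sp), rg, me, db, e.n_correct, e.n_total,
                 e.accuracy)
                for (sp, rg, me, db), e in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["species", "region", "method",
                                           "database", "n_correct", "n_total",
                                           "accuracy"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "AccuracyTable":
        df = pd.read_csv(path, sep="\t")
        table = AccuracyTable()
        for r in df.itertuples():
            key = (_spkey(r.species), r.region, r.method, r.database)
            table.entries[key] = AccuracyEntry(int(r.n_correct), int(r.n_total))
            table.display.setdefault(_spkey(r.species), r.species)
        return table


def score_accuracy(truth: Mapping[str, str],
                   grouped: Mapping[tuple[str, str, str],
                                    Sequence[ClassificationResult]],
                   table: AccuracyTable | None = None) -> AccuracyTable:
    """Score species-level accuracy against a query→species truth map.

    ``grouped`` maps (region, method, database) to that pipeline's
    predictions.  A prediction is correct iff its normalized species binomial
    equals the truth species (case-insensitive); a lineage truncated above
    species counts as incorrect.  Predictions for unknown queries raise.
    """
    table = table if table is not None else AccuracyTable()
    for (region, method, database), results in grouped.items():
        for r in results:
            if r.query_id not in truth:
                raise KeyError(f"prediction for unknown query {r.query_id!r}")
            true_sp = truth[r.query_id]
            correct = bool(r.species) and _spkey(r.species) == _spkey(true_sp)
            table.add(true_sp, region, method, database, correct)
    return table


@dataclass
class CombinedLookup:
    """species → authoritative database for one (region, method).

    ``accuracies`` snapshots the per-(species, database) accuracy of the
    source table so inference-time conflicts can be broken by accuracy;
    ``flagged`` lists species mapped by priority alone (all-zero accuracy).
    """

    region: str
    method: str
    mapping: dict[str, str]
    priority: tuple[str, ...]
    accuracies: dict[str, dict[str, float]] = field(default_factory=dict)
    flagged: frozenset[str] = frozenset()
    provenance: str = ""

    def database_for(self, species: str) -> str | None:
        return self.mapping.get(_spkey(species))

    def to_json(self, path: str | Path) -> None:
        payload = {"region": self.region, "method": self.method,
                   "mapping": self.mapping, "priority": list(self.priority),
                   "accuracies": self.accuracies,
                   "flagged": sorted(self.flagged),
                   "provenance": self.provenance}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "CombinedLookup":
        d = json.loads(Path(path).read_text())
        return CombinedLookup(region=d["region"], method=d["method"],
                              mapping=d["mapping"],
                              priority=tuple(d["priority"]),
                              accuracies=d["accuracies"],
                              flagged=frozenset(d["flagged"]),
                              provenance=d.get("provenance", ""))


#: default database priority for tie-breaking
DEFAULT_PRIORITY: tuple[str, ...] = ("rdp", "silva", "greengenes2")


def build_lookup(table: AccuracyTable, region: str, method: str,
                 priority: Sequence[str] = DEFAULT_PRIORITY) -> CombinedLookup:
    """Map every scored species to its argmax-accuracy database.

    A species absent from one database's predictions is treated as accuracy 0
    there; exact ties go to the earliest database in ``priority``; species
    with all-zero accuracy are mapped to the priority head and flagged.
    """
    databases = table.databases_for(region, method)
    if not databases:
        raise ValueError(f"no databases scored for ({region}, {method})")
    ordered = [db for db in priority if db in databases]
    ordered += [db for db in databases if db not in ordered]

    mapping: dict[str, str] = {}
    accuracies: dict[str, dict[str, float]] = {}
    flagged: set[str] = set()
    for sp in table.species_for(region, method):
        acc = {db: table.accuracy(sp, region, method, db) for db in ordered}
        accuracies[sp] = acc
        best = max(ordered, key=lambda db: (acc[db], -ordered.index(db)))
        mapping[sp] = best
        if acc[best] == 0.0:
            flagged.add(sp)
    return CombinedLookup(region=region, method=method, mapping=mapping,
                          priority=tuple(ordered), accuracies=accuracies,
                          flagged=frozenset(flagged))


def combine_classifications(per_db: Mapping[str, ClassificationResult],
                            lookup: CombinedLookup,
                            fallback_db: str) -> ClassificationResult:
    """Merge one query's per-database results under the authority rule.

    A database's species call enters the candidate set only when the lookup
    designates that database as the authority for the species it called.
    One candidate → returned as-is (flagged ``combined``); several → the one
    with the highest (species, database) accuracy in the source table, ties
    by priority; none → the fallback database's result flagged ``fallback``.
    """
    qids = {r.query_id for r in per_db.values()}
    if len(qids) > 1:
        raise ValueError(f"results refer to different queries: {sorted(qids)}")
    for db in set(lookup.mapping.values()):
        if db not in per_db:
            raise KeyError(f"missing result for database {db!r} named in lookup")

    candidates: list[tuple[str, ClassificationResult]] = []
    for db, res in per_db.items():
        sp = res.species
        if sp and lookup.database_for(sp) == db:
            candidates.append((db, res))

    if not candidates:
        if fallback_db not in per_db:
            raise KeyError(f"fallback database {fallback_db!r} has no result")
        base = per_db[fallback_db]
        return ClassificationResult(base.query_id, base.lineage, base.confidence,
                                    base.method, base.database,
                                    flags=base.flags + ("combined", "fallback"))

    def rank(item: tuple[str, ClassificationResult]):
        db, res = item
        acc = lookup.accuracies.get(_spkey(res.species), {}).get(db, 0.0)
        prio = lookup.priority.index(db) if db in lookup.priority else len(lookup.priority)
        return (-acc, prio)

    db, best = min(candidates, key=rank)
    return ClassificationResult(best.query_id, best.lineage, best.confidence,
                                best.method, best.database,
                                flags=best.flags + ("combined",))


def combine_all(per_db_results: Mapping[str, Sequence[ClassificationResult]],
                lookup: CombinedLookup, fallback_db: str
                ) -> list[ClassificationResult]:
    """Apply :func:`combine_classifications` query-by-query over aligned lists."""
    by_query: dict[str, dict[str, ClassificationResult]] = {}
    order: list[str] = []
    for db, results in per_db_results.items():
        for r in results:
            if r.query_id not in by_query:
                order.append(r.query_id)
            by_query.setdefault(r.query_id, {})[db] = r
    return [combine_classifications(by_query[q], lookup, fallback_db)
            for q in order]
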