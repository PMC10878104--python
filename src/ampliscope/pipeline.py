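"""End-to-end evaluation designs.

Two orchestrations mirror how region/classifier/database benchmarking is
done in practice:

* :func:`run_evaluation` — in-silico evaluation: amplify each reference
  database per region, train/classify every (method × database) pipeline on
  query amplicons with known species, score per-species accuracy, build the
  species→best-database lookup and re-score the combined pipeline.
* :func:`run_mock_comparison` — mock-community comparison: simulate reads per
  region and for the full-length gene, classify, build abundance profiles,
  and compare each region's profiles to the full-length truth with four
  dissimilarities, species-recovery counts and a pooled PCoA.

Every run is fully reproducible from the config plus its seed; a hash of the
config is embedded in all tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifiers import (ClassificationResult, TopHitClassifier, classify_nb,
                          train_nb)
from .community_eval import (METRICS, AbundanceProfile, PCoAResult,
                             dissimilarity, distance_matrix, pcoa,
                             profile_from_classifications)
from .consensus import (AccuracyTable, CombinedLookup, DEFAULT_PRIORITY,
                        build_lookup, combine_all, score_accuracy)
from .insilico_pcr import FULL_LENGTH, amplify, amplify_database, builtin_panel
from .reference_io import ReferenceDatabase, ReferenceRecord
from .synthetic_data import (MockCommunitySpec, ReferenceWorld, _child_rng,
                             _mutate, block_layout, make_reference_world,
                             VARIABLE_BLOCKS)

log = logging.getLogger("ampliscope")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Invalid or missing input data (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Declarative description of one evaluation run."""

    regions: tuple[str, ...] = ("V1-V3",)
    methods: tuple[str, ...] = ("nb",)
    databases: tuple[str, ...] = ("greengenes2", "silva", "rdp")
    seed: int = 0
    # synthetic world
    n_species: int = 12
    n_sister_pairs: int = 2
    n_records_per_species: int = 3
    record_mutation_rate: float = 0.005
    divergence: float = 0.25
    dropout: dict = field(default_factory=dict)
    # queries
    n_queries_per_species: int = 5
    query_mutation_rate: float = 0.01
    # classifier parameters
    k: int = 8
    alpha: float = 0.001
    confidence_threshold: float = 0.7
    n_bootstrap: int = 100
    min_identity: float = 0.97
    max_accepts: int = 10
    consensus_threshold: float = 0.51
    # read truncation (None = full amplicons)
    truncate_to: int | None = None
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    outdir: str | None = None

    def __post_init__(self) -> None:
        panel = builtin_panel()
        for r in self.regions:
            if r not in panel:
                raise ConfigError(f"unknown region {r!r}")
        for m in self.methods:
            if m not in ("nb", "tophit"):
                raise ConfigError(f"unknown method {m!r} (nb|tophit)")
        if self.n_queries_per_species < 1:
            raise ConfigError("n_queries_per_species must be ≥ 1")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regions", "methods", "databases", "priority"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def region_database(db: ReferenceDatabase, region: str,
                    **amplify_params) -> ReferenceDatabase:
    """Extract a region-trimmed reference database by in-silico PCR."""
    if region == FULL_LENGTH:
        pass  # full-length still goes through amplification (primer-trimmed)
    pset = builtin_panel()[region]
    amps, _ = amplify_database(db, pset, **amplify_params)
    lineages = {r.id: r.lineage for r in db.records}
    records = [ReferenceRecord(f"{a.source_id}|{i}", a.sequence,
                               lineages[a.source_id])
               for i, a in enumerate(amps)]
    if not records:
        raise DataError(f"database {db.name!r}: no record amplifies {region}")
    return ReferenceDatabase(name=db.name, records=records, dialect=db.dialect)


def make_queries(world: ReferenceWorld, region: str, n_per_species: int,
                 mutation_rate: float, seed: int,
                 truncate_to: int | None = None
                 ) -> tuple[dict[str, str], dict[str, str]]:
    """Mutated amplicon queries with known truth.

    Each query is the species' truth sequence with substitutions confined to
    variable blocks, then amplified for the region; species whose region was
    knocked out simply yield no queries.  Returns (queries, truth).
    """
    layout = block_layout()
    var_positions = np.concatenate([np.arange(*layout[b])
                                    for b in VARIABLE_BLOCKS])
    pset = builtin_panel()[region]
    rng = _child_rng(seed, "queries", region)
    queries: dict[str, str] = {}
    truth: dict[str, str] = {}
    for sp in world.species:
        base = world.truth_sequences[sp]
        for j in range(n_per_species):
            mutated = _mutate(base, mutation_rate, rng, positions=var_positions)
            hits = amplify((sp, mutated), pset)
            if not hits:
                continue
            qid = f"{sp.replace(' ', '_')}|{region}|q{j}"
            seq = hits[0].sequence
            if truncate_to is not None:
                seq = seq[:truncate_to]
            queries[qid] = seq
            truth[qid] = sp
    return queries, truth


@dataclass
class EvaluationResult:
    config: RunConfig
    table: AccuracyTable
    lookups: dict[tuple[str, str], CombinedLookup]
    summary: pd.DataFrame
    predictions: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.config.hash()
        for name, df in (("summary.tsv", self.summary),
                         ("predictions.tsv", self.predictions),
                         ("accuracy_table.tsv", self.table.to_frame())):
            with open(outdir / name, "wt") as fh:
                fh.write(f"# config-hash: {h}\n")
                df.to_csv(fh, sep="\t", index=False)
        for (region, method), lookup in self.lookups.items():
            lookup.to_json(outdir / f"lookup_{region}_{method}.json")


def _classify_region(world: ReferenceWorld, cfg: RunConfig, region: str,
                     queries: dict[str, str]
                     ) -> dict[tuple[str, str, str], list[ClassificationResult]]:
    """All (method × database) classifications for one region's queries."""
    grouped: dict[tuple[str, str, str], list[ClassificationResult]] = {}
    for db_name in cfg.databases:
        if db_name not in world.databases:
            raise DataError(f"world has no database {db_name!r}")
        rdb = region_database(world.databases[db_name], region)
        for method in cfg.methods:
            results: list[ClassificationResult] = []
            if method == "nb":
                model = train_nb(rdb, k=cfg.k, alpha=cfg.alpha)
                for i, (qid, seq) in enumerate(queries.items()):
                    results.append(classify_nb(
                        model, seq, query_id=qid,
                        confidence_threshold=cfg.confidence_threshold,
                        n_bootstrap=cfg.n_bootstrap,
                        seed=(cfg.seed + 31 * i) % (2 ** 31)))
            else:
                th = TopHitClassifier(rdb, k=cfg.k)
                for qid, seq in queries.items():
                    results.append(th.classify(
                        seq, query_id=qid, min_identity=cfg.min_identity,
                        max_accepts=cfg.max_accepts,
                        consensus_threshold=cfg.consensus_threshold))
            grouped[(region, method, db_name)] = results
            log.info("classified region=%s method=%s db=%s queries=%d",
                     region, method, db_name, len(results))
    return grouped


def run_evaluation(cfg: RunConfig, world: ReferenceWorld | None = None
                   ) -> EvaluationResult:
    """Amplify → classify (method × database) → score → combine → re-score.

    The summary has one row per (region, method, database ∪ {combined},
    species subset) with the across-species mean ± sd accuracy.
    """
    if world is None:
        world = make_reference_world(
            n_species=cfg.n_species, n_sister_pairs=cfg.n_sister_pairs,
            seed=cfg.seed, n_records_per_species=cfg.n_records_per_species,
            record_mutation_rate=cfg.record_mutation_rate,
            dropout=cfg.dropout, divergence=cfg.divergence)
    table = AccuracyTable()
    lookups: dict[tuple[str, str], CombinedLookup] = {}
    pred_rows: list[tuple] = []

    for region in cfg.regions:
        queries, truth = make_queries(
            world, region, cfg.n_queries_per_species, cfg.query_mutation_rate,
            cfg.seed, truncate_to=cfg.truncate_to)
        if not queries:
            raise DataError(f"no queries amplified for region {region}")
        log.info("region=%s queries=%d", region, len(queries))
        grouped = _classify_region(world, cfg, region, queries)
        score_accuracy(truth, grouped, table)

        for method in cfg.methods:
            lookup = build_lookup(table, region, method, cfg.priority)
            lookups[(region, method)] = lookup
            per_db = {db: grouped[(region, method, db)] for db in cfg.databases}
            fallback = _best_single_db(table, region, method, cfg)
            combined = combine_all(per_db, lookup, fallback)
            score_accuracy(truth, {(region, method, "combined"): combined}, table)
            for db, results in list(per_db.items()) + [("combined", combined)]:
                for r in results:
                    pred_rows.append((r.query_id, truth[r.query_id], region,
                                      method, db, r.lineage.key(),
                                      round(r.confidence, 4),
                                      ",".join(r.flags)))

    summary = _summarize(table, cfg)
    predictions = pd.DataFrame(
        pred_rows, columns=["query_id", "true_species", "region", "method",
                            "database", "predicted_lineage", "confidence",
                            "flags"])
    result = EvaluationResult(config=cfg, table=table, lookups=lookups,
                              summary=summary, predictions=predictions)
    if cfg.outdir:
        result.write(cfg.outdir)
    return result


def _best_single_db(table: AccuracyTable, region: str, method: str,
                    cfg: RunConfig) -> str:
    """Fallback database: the best overall single pipeline for the region."""
    means = {db: table.pipeline_summary(region, method, db)[0]
             for db in cfg.databases}
    best = max(means.values())
    for db in cfg.priority:
        if db in means and means[db] == best:
            return db
    return max(means, key=lambda d: means[d])


def _summarize(table: AccuracyTable, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for region in cfg.regions:
        for method in cfg.methods:
            for db in list(cfg.databases) + ["combined"]:
                for subset in (None, "key_lactobacillus"):
                    try:
                        mean, sd, n = table.pipeline_summary(region, method, db,
                                                             subset)
                    except (ValueError, KeyError):
                        continue
                    rows.append((region, method, db,
                                 subset or "all_species", mean, sd, n))
    return pd.DataFrame(rows, columns=["region", "method", "database",
                                       "subset", "mean_accuracy",
                                       "sd_accuracy", "n_species"])


# ---------------------------------------------------------------------------
# Benchmark experiments
# ---------------------------------------------------------------------------

def combined_uplift(seed: int, region: str = "V1-V3", method: str = "nb",
                    **cfg_kwargs) -> dict[str, float]:
    """Mean across-species accuracy of each single database and the combined
    pipeline on one synthetic world (the lookup-building set)."""
    cfg = RunConfig(regions=(region,), methods=(method,), seed=seed,
                    **cfg_kwargs)
    res = run_evaluation(cfg)
    out = {db: res.table.pipeline_summary(region, method, db)[0]
           for db in cfg.databases}
    out["combined"] = res.table.pipeline_summary(region, method, "combined")[0]
    return out


def truncation_robustness(seed: int, region: str = "V1-V3",
                          read_length: int = 223,
                          n_queries_per_species: int = 5,
                          query_mutation_rate: float = 0.01,
                          k: int = 8) -> tuple[float, float]:
    """Mean species accuracy on full region amplicons vs their forward-read
    prefixes, classified with one model trained on the full amplicons of a
    defect-free reference database.  Returns (full, truncated)."""
    world = make_reference_world(seed=seed)
    rdb = region_database(world.truth_database(), region)
    model = train_nb(rdb, k=k)
    queries, truth = make_queries(world, region, n_queries_per_species,
                                  query_mutation_rate, seed)

    def accuracy(qs: Mapping[str, str]) -> float:
        per_species: dict[str, list[bool]] = {}
        for i, (qid, seq) in enumerate(qs.items()):
            r = classify_nb(model, seq, query_id=qid,
                            seed=(seed + 13 * i) % (2 ** 31))
            per_species.setdefault(truth[qid], []).append(
                r.species.lower() == truth[qid].lower())
        return float(np.mean([np.mean(v) for v in per_species.values()]))

    full = accuracy(queries)
    truncated = accuracy({q: s[:read_length] for q, s in queries.items()})
    return full, truncated


# ---------------------------------------------------------------------------
# Mock-community comparison
# ---------------------------------------------------------------------------

@dataclass
class MockComparisonResult:
    config: RunConfig
    profiles: dict[tuple[str, str], AbundanceProfile]   # (sample, region|full)
    dissimilarities: pd.DataFrame
    recovery: pd.DataFrame
    pcoa: dict[str, PCoAResult]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = self.config.hash()
        for name, df in (("dissimilarity.tsv", self.dissimilarities),
                         ("species_recovery.tsv", self.recovery)):
            with open(outdir / name, "wt") as fh:
                fh.write(f"# config-hash: {h}\n")
                df.to_csv(fh, sep="\t", index=False)
        for metric, res in self.pcoa.items():
            coords = pd.DataFrame(
                res.coordinates,
                index=res.sample_ids,
                columns=[f"PC{i+1}" for i in range(res.coordinates.shape[1])])
            coords.to_csv(outdir / f"pcoa_{metric}.tsv", sep="\t",
                          index_label="sample")
            (outdir / f"pcoa_{metric}_eigenvalues.json").write_text(
                json.dumps({"eigenvalues": res.eigenvalues.tolist(),
                            "proportion_explained":
                                res.proportion_explained.tolist()}))


def run_mock_comparison(cfg: RunConfig, mocks: Sequence[MockCommunitySpec],
                        world: ReferenceWorld | None = None,
                        error_rate: float | None = None,
                        reads_bootstrap: int = 0) -> MockComparisonResult:
    """Compare per-region community profiles against full-length truth.

    For every mock sample, full-length and per-region reads are simulated,
    classified with the naive Bayes model trained on the defect-free truth
    database (region-trimmed), and turned into profiles.  Outputs per
    (sample, region): the four dissimilarities to the full-length profile
    and the species-recovery count; plus a pooled PCoA per metric over all
    profiles.  A region in which a sample yields no classified reads is
    recorded as missing, not fatal.
    """
    from .synthetic_data import simulate_reads

    if world is None:
        world = make_reference_world(
            n_species=cfg.n_species, n_sister_pairs=cfg.n_sister_pairs,
            seed=cfg.seed, n_records_per_species=cfg.n_records_per_species,
            record_mutation_rate=cfg.record_mutation_rate,
            dropout=cfg.dropout, divergence=cfg.divergence)
    truth_db = world.truth_database()
    regions = [r for r in cfg.regions if r != FULL_LENGTH]
    all_regions = [FULL_LENGTH] + regions

    models = {}
    for region in all_regions:
        rdb = region_database(truth_db, region)
        models[region] = train_nb(rdb, k=cfg.k, alpha=cfg.alpha)

    profiles: dict[tuple[str, str], AbundanceProfile] = {}
    rows = []
    recovery_rows = []
    for mock in mocks:
        for region in all_regions:
            reads, _ = simulate_reads(world, mock, region)
            results = []
            for i, (rid, seq) in enumerate(reads.items()):
                results.append(classify_nb(
                    models[region], seq, query_id=rid,
                    confidence_threshold=cfg.confidence_threshold,
                    n_bootstrap=reads_bootstrap,
                    seed=(mock.seed + 17 * i) % (2 ** 31)))
            if not results:
                log.warning("sample=%s region=%s: zero classified reads",
                            mock.sample_id, region)
                continue
            profiles[(mock.sample_id, region)] = profile_from_classifications(
                results, f"{mock.sample_id}|{region}")
            log.info("sample=%s region=%s reads=%d", mock.sample_id, region,
                     len(results))

    for mock in mocks:
        full = profiles.get((mock.sample_id, FULL_LENGTH))
        if full is None:
            continue
        truth_species = {sp for sp, ab in mock.abundances.items() if ab > 0}
        for region in regions:
            prof = profiles.get((mock.sample_id, region))
            if prof is None:
                rows.append((mock.sample_id, region) + (np.nan,) * len(METRICS))
                recovery_rows.append((mock.sample_id, region, 0,
                                      len(truth_species)))
                continue
            vals = tuple(dissimilarity(prof, full, m) for m in METRICS)
            rows.append((mock.sample_id, region) + vals)
            detected = {sp for sp, ab in prof.abundances.items() if ab > 0}
            recovery_rows.append((mock.sample_id, region,
                                  len(truth_species & detected),
                                  len(truth_species)))

    diss = pd.DataFrame(rows, columns=["sample_id", "region"] + list(METRICS))
    recovery = pd.DataFrame(recovery_rows, columns=["sample_id", "region",
                                                    "n_recovered", "n_truth"])
    ordered = [p for p in profiles.values()]
    pcoas: dict[str, PCoAResult] = {}
    if len(ordered) >= 2:
        for metric in METRICS:
            ids, dmat = distance_matrix(ordered, metric)
            pcoas[metric] = pcoa(dmat, sample_ids=ids)

    result = MockComparisonResult(config=cfg, profiles=profiles,
                                  dissimilarities=diss, recovery=recovery,
                                  pcoa=pcoas)
    if cfg.outdir:
        result.write(cfg.outdir)
    return result
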