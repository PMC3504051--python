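"""End-to-end orchestration: generate -> featurize -> simulate -> model -> report.

A single :class:`RunConfig` drives the whole analysis; every random
stage derives its seed deterministically from the master seed, so the
same configuration reproduces the same results tree (the manifest
records seeds and output checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import descriptors as desc
from . import model_selection as msel
from . import rf_validation as rfv
from . import stats_reports as stats
from . import synthetic_data as syn
from .errors import ConfigurationError
from .snb import DEFAULT_FOLDS

log = logging.getLogger("fragmind")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults = study conditions)."""

    n_fragments: int = 3700
    n_batches: int = 8
    n_duplicates: int = 227
    noise_rate: float = 0.05
    delta_roc: float = msel.DEFAULT_DELTA
    rf_z_cutoff: float = rfv.DEFAULT_Z_CUTOFF
    consensus_threshold: float = 0.75
    max_combo: int = 4
    enrich_threshold: float = 0.6
    rf_trees: int = 500
    rf_trials: int = 3
    self_report_extra: int = 6
    master_seed: int = 0
    include_rule_selectors: bool = True
    include_strategy_selectors: bool = True
    include_random_selectors: bool = True
    run_rf: bool = True
    run_benchmark: bool = True

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration errors (empty list = valid)."""
    errors = []
    if config.n_fragments < 1:
        errors.append("n_fragments must be >= 1")
    if config.n_batches < 2:
        errors.append("n_batches must be >= 2")
    if config.n_duplicates >= config.n_fragments:
        errors.append("n_duplicates must be < n_fragments")
    if not 0.0 <= config.noise_rate <= 1.0:
        errors.append("noise_rate must be in [0, 1]")
    if not 0.5 < config.consensus_threshold <= 1.0:
        errors.append("consensus_threshold must be in (0.5, 1]")
    if config.delta_roc < 0:
        errors.append("delta_roc must be >= 0")
    if config.rf_z_cutoff <= 0:
        errors.append("rf_z_cutoff must be > 0")
    if config.max_combo < 1:
        errors.append("max_combo must be >= 1")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis, writing a reproducible results tree."""
    errors = validate_config(config)
    if errors:
        raise ConfigurationError("; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "seeds": {}, "stages": {}, "checksums": {}}

    def _stage(name):
        t0 = time.time()
        log.info("stage %s", name)
        return t0

    def _done(name, t0):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}

    t0 = _stage("fragments")
    seed = config.stage_seed("fragments")
    manifest["seeds"]["fragments"] = seed
    fragments = syn.generate_fragments(config.n_fragments, seed)
    fragments = syn.assign_batches(
        fragments, config.n_batches, config.n_duplicates, config.stage_seed("batches")
    )
    fragments.to_csv(out / "fragments.csv")
    fragments.to_smiles_file(out / "fragments.smi")
    _done("fragments", t0)

    t0 = _stage("descriptors")
    table = desc.compute_descriptors(fragments)
    table.to_csv(out / "descriptors.csv")
    _done("descriptors", t0)

    t0 = _stage("selectors")
    roster = []
    if config.include_rule_selectors:
        roster += syn.ruleset_selectors(config.noise_rate, config.stage_seed("rules"))
    if config.include_strategy_selectors:
        roster += syn.strategy_selectors(config.noise_rate, config.stage_seed("strategies"))
    if config.include_random_selectors:
        roster += syn.random_selectors(seed=config.stage_seed("random"))
    if not roster:
        log.warning("no selectors configured; stopping after descriptors")
        _write_manifest(manifest, out)
        return out
    syn.selectors_to_json(roster, out / "selectors.json")
    matrix = syn.build_selection_matrix(roster, fragments, table)
    matrix.to_csv(out / "selections.csv")
    reports = {
        s.selector_id: sorted(
            syn.simulate_self_report(s, config.self_report_extra, config.stage_seed(f"report:{s.selector_id}"))
        )
        for s in roster
        if s.rule is not None
    }
    (out / "self_reports.json").write_text(json.dumps(reports, indent=1))
    _done("selectors", t0)

    t0 = _stage("snb_search")
    pres = fragments.presentations()
    ecfp_sets = {fid: desc.ecfp_features(smi) for fid, smi in zip(fragments.fragment_ids, fragments.smiles)}
    search_results = {}
    for sel in roster:
        sel_dir = out / "selectors" / sel.selector_id
        sel_dir.mkdir(parents=True, exist_ok=True)
        result = msel.run_subset_search(
            matrix.row(sel.selector_id),
            pres,
            table,
            delta=config.delta_roc,
            max_combo=config.max_combo,
            enrich_threshold=config.enrich_threshold,
        )
        payload = json.loads(result.to_json())
        if config.run_benchmark:
            from .snb import train_benchmark_nb

            payload["benchmark_roc"] = train_benchmark_nb(
                matrix.row(sel.selector_id), pres, table, ecfp_sets
            ).mean_roc
        (sel_dir / "snb_search.json").write_text(json.dumps(payload, indent=1))
        search_results[sel.selector_id] = result
    _done("snb_search", t0)

    if config.run_rf:
        t0 = _stage("rf_validation")
        hyper = rfv.RFHyperparams(n_trees=config.rf_trees)
        for sel in roster:
            importance, mean_roc = rfv.rf_validate(
                matrix.row(sel.selector_id),
                pres,
                table,
                hyper,
                n_trials=config.rf_trials,
                seed=config.stage_seed(f"rf:{sel.selector_id}"),
                cutoff=config.rf_z_cutoff,
            )
            primary, secondary = rfv.rf_parameters(importance, table)
            payload = json.loads(importance.to_json())
            payload.update(
                {"mean_roc": mean_roc, "primary_parameter": primary, "secondary_parameters": sorted(secondary)}
            )
            (out / "selectors" / sel.selector_id / "rf_validation.json").write_text(
                json.dumps(payload, indent=1)
            )
        _done("rf_validation", t0)

    t0 = _stage("consensus")
    cons_dir = out / "consensus"
    cons_dir.mkdir(exist_ok=True)
    cns.similarity_matrix(matrix).to_csv(cons_dir / "similarity.csv")
    cns.consistency(matrix, fragments).to_csv(cons_dir / "consistency.csv")
    fractions = cns.agreement_fractions(matrix)
    fractions.to_csv(cons_dir / "agreement.csv")
    votes = cns.consensus_vote(fractions, config.consensus_threshold)
    votes.to_csv(cons_dir / "votes.csv")
    high_agreement = votes.index[votes != "none"]
    if len(high_agreement) >= 2:
        ccm = cns.ccm_fit(cns.restrict_to_fragments(matrix, high_agreement))
        ccm.to_json(cons_dir / "ccm.json")
    if (votes == "consensus-good").any() or (votes == "consensus-bad").any():
        good, bad = cns.consensus_feature_extraction(votes, ecfp_sets)
        good.to_csv(cons_dir / "consensus_features_desirable.csv", index=False)
        bad.to_csv(cons_dir / "consensus_features_undesirable.csv", index=False)
    _done("consensus", t0)

    t0 = _stage("stats")
    per_batch, cohort = stats.pass_fraction_summary(matrix)
    per_batch.to_csv(out / "pass_fractions.csv")
    rule_ids = [s.selector_id for s in roster if s.rule is not None]
    model_counts = [len(search_results[r].selected_parameters) for r in rule_ids]
    reported_counts = [len(reports[r]) for r in rule_ids]
    stats_out = {"pass_fractions": cohort}
    try:
        t = stats.paired_count_ttest(reported_counts, model_counts)
        stats_out["reported_vs_model_counts"] = {"t": t.statistic, "p": t.p_value, "tail": t.tail}
    except Exception as exc:  # degenerate with tiny rosters
        stats_out["reported_vs_model_counts"] = {"error": str(exc)}
    fisher = {}
    for cls in desc.PARAMETER_CLASSES:
        uses = [cls in search_results[r].selected_parameters for r in rule_ids]
        reps = [cls in reports[r] for r in rule_ids]
        if any(uses) or any(reps):
            fisher[cls] = stats.fisher_param_independence(np.array(uses), np.array(reps)).p_value
    stats_out["fisher_model_vs_report"] = fisher
    (out / "stats.json").write_text(json.dumps(stats_out, indent=1))
    _done("stats", t0)

    _write_manifest(manifest, out)
    return out


def _write_manifest(manifest: dict, out: Path) -> None:
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
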