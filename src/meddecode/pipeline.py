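"""End-to-end orchestration: config validation, the canonical analysis chain,
and report aggregation.

The canonical chain mirrors the study's Results sequence per group:
simulate -> preprocess -> connectivity features -> repeated-split decoding ->
permutation significance (Bonferroni over the two groups) -> group
comparison (Mann-Whitney on fold accuracies, Bayesian correlated t-test vs a
chance classifier) -> sample-size bootstrap -> age-regression control ->
selection-probability / weight / hemisphere relevance.  Every stage writes
its result artifact (JSON/CSV/TSV) into the run directory, stamped with the
config hash, and ``report`` aggregates the artifacts without computing
anything new.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .connectivity import assemble_dataset
from .decoding import CVConfig, run_cv
from .inference import (bayesian_correlated_ttest, bonferroni,
                        bootstrap_subsample, mann_whitney, permutation_test,
                        regress_out_age)
from .io import config_hash, sim_config_from_dict, sim_config_to_dict
from .parcellation import build_edge_table, load_parcellation
from .preprocess import preprocess_study
from .relevance import (hemispheric_analysis, network_relevance,
                        relevant_feature_fstats, selection_probability,
                        stable_edges, weight_map)
from .synthetic import SimulationConfig, generate_study
from .util import ConfigurationError, log


@dataclass(frozen=True)
class InferenceConfig:
    n_perm: int = 200
    scheme: str = "within_subject"
    correction: str = "add_one"
    perm_cv_repetitions: int | None = None  # None -> cv.n_repetitions
    n_boot: int = 100
    boot_cv_repetitions: int | None = None
    rho: float = 0.25
    bonferroni_m: int = 2
    age_control: bool = True


@dataclass(frozen=True)
class RelevanceConfig:
    stability_threshold: float = 1.0
    weight_norm: str = "l2"
    hemi_n_perm: int = 200


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    parcellation_path: str | None = None  # None -> bundled 90-ROI fixture
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    relevance: RelevanceConfig = field(default_factory=RelevanceConfig)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "parcellation_path": self.parcellation_path,
            "simulation": sim_config_to_dict(self.simulation),
            "cv": dataclasses.asdict(self.cv),
            "inference": dataclasses.asdict(self.inference),
            "relevance": dataclasses.asdict(self.relevance),
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _build_section(cls, payload: dict[str, Any], name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    return cls(**payload)


def config_from_dict(payload: dict[str, Any]) -> RunConfig:
    payload = dict(payload or {})
    top_allowed = {"seed", "parcellation_path", "simulation", "cv",
                   "inference", "relevance"}
    unknown = set(payload) - top_allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    seed = payload.get("seed", 0)
    sim = payload.get("simulation", {})
    sim.setdefault("seed", seed)
    return RunConfig(
        seed=seed,
        parcellation_path=payload.get("parcellation_path"),
        simulation=sim_config_from_dict(sim),
        cv=_build_section(CVConfig, {"seed": seed, **payload.get("cv", {})}, "cv"),
        inference=_build_section(InferenceConfig, payload.get("inference", {}),
                                 "inference"),
        relevance=_build_section(RelevanceConfig, payload.get("relevance", {}),
                                 "relevance"),
    )


def validate_config(path: str | Path | None) -> RunConfig:
    """Parse and schema-check a YAML run config; empty file -> all defaults."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("run config must be a YAML mapping")
    return config_from_dict(payload)


def _write(outdir: Path, name: str, payload: dict[str, Any],
           cfg_hash: str) -> None:
    payload = {"config_hash": cfg_hash, **payload}
    (outdir / name).write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_full_study(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full two-group analysis; returns the aggregated report.

    Deterministic given (config, seed).  Stage results are written as
    artifacts into ``outdir``; time series stay in memory (the CLI
    ``simulate``/``preprocess`` subcommands provide file-based handoffs when
    stages must run in isolation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    (outdir / "config_echo.json").write_text(
        json.dumps({"config_hash": cfg_hash, "config": config.to_dict()},
                   indent=1))
    parcellation = load_parcellation(config.parcellation_path)
    edges = build_edge_table(parcellation)
    log.info("run_full_study: seed=%d hash=%s", config.seed, cfg_hash)

    study = generate_study(parcellation, config.simulation)
    preprocess_study(study)

    groups = sorted(config.simulation.n_subjects)
    inf, rel = config.inference, config.relevance
    perm_cv = replace(config.cv,
                      n_repetitions=inf.perm_cv_repetitions or config.cv.n_repetitions)
    boot_cv = replace(config.cv,
                      n_repetitions=inf.boot_cv_repetitions or config.cv.n_repetitions)

    datasets, cv_results, perms = {}, {}, {}
    for group in groups:
        gdir = outdir / group
        gdir.mkdir(exist_ok=True)
        ds = assemble_dataset(study, group)
        datasets[group] = ds
        cv = run_cv(ds, config.cv)
        cv_results[group] = cv
        cv.to_json(gdir / "cv_result.json")
        observed = run_cv(ds, perm_cv).mean_accuracy if perm_cv != config.cv else cv.mean_accuracy
        perm = permutation_test(ds, perm_cv, n_perm=inf.n_perm,
                                scheme=inf.scheme, correction=inf.correction,
                                seed=config.seed, observed=observed)
        perms[group] = perm
        _write(gdir, "permutation.json", {
            "observed": perm.observed, "p_value": perm.p_value,
            "n_perm": perm.n_perm, "scheme": perm.scheme,
            "correction": perm.correction,
            "null_mean": float(perm.null_accuracies.mean()),
            "null_accuracies": perm.null_accuracies}, cfg_hash)

        sp = selection_probability(cv, edges)
        np.savetxt(gdir / "selection_probability.csv", sp.matrix,
                   delimiter=",", fmt="%.6g")
        nr = network_relevance(sp, parcellation, edges)
        nr.to_frame().to_csv(gdir / "network_relevance.csv")
        stable = stable_edges(sp, rel.stability_threshold)
        wm = weight_map(cv, stable, weight_norm=rel.weight_norm)
        wm.to_frame(edges).to_csv(gdir / "stable_edges.tsv", sep="\t",
                                  index=False)
        hemi = hemispheric_analysis(wm, edges, parcellation,
                                    n_perm=rel.hemi_n_perm, seed=config.seed)
        min_f = None
        if stable.size:
            fstats = relevant_feature_fstats(ds, stable)
            fstats.to_csv(gdir / "stable_edge_fstats.tsv", sep="\t", index=False)
            min_f = float(fstats["F"].min())
        _write(gdir, "relevance.json", {
            "n_stable_edges": int(stable.size),
            "stable_edges": stable,
            "min_stable_F": min_f,
            "selection_probability_mass": float(sp.per_edge.sum()),
            "hemisphere_counts": hemi.counts,
            "hemisphere_mw_U": hemi.mw_U, "hemisphere_mw_p": hemi.mw_p,
            "hemisphere_count_p": hemi.count_p, "note": hemi.note}, cfg_hash)

    p_adj = bonferroni([perms[g].p_value for g in groups], inf.bonferroni_m)
    mw = mann_whitney(cv_results[groups[0]].accuracies,
                      cv_results[groups[1]].accuracies,
                      alternative="two-sided")
    bayes = {g: bayesian_correlated_ttest(cv_results[g].accuracies,
                                          comparator=0.5, rho=inf.rho)
             for g in groups}
    _write(outdir, "group_comparison.json", {
        "groups": groups,
        "mann_whitney_U": mw.U, "mann_whitney_p": mw.p_value,
        "n1": mw.n1, "n2": mw.n2,
        "bayes_p_greater": {g: bayes[g].p_greater for g in groups},
        "p_bonferroni": {g: float(p_adj[k]) for k, g in enumerate(groups)}},
        cfg_hash)

    boot_payload = None
    sizes = {g: len(datasets[g].subjects) for g in groups}
    big = max(sizes, key=sizes.get)
    small = min(sizes, key=sizes.get)
    if sizes[big] > sizes[small]:
        boot = bootstrap_subsample(datasets[big], sizes[small], boot_cv,
                                   n_boot=inf.n_boot, seed=config.seed)
        boot_payload = {
            "group": big, "target_n_subjects": sizes[small],
            "n_boot": inf.n_boot,
            "mean_accuracy": float(boot.accuracies.mean()),
            "percentile_of_small_group": boot.percentile_of(
                cv_results[small].mean_accuracy),
            "percentile_of_big_group": boot.percentile_of(
                cv_results[big].mean_accuracy),
            "accuracies": boot.accuracies}
        _write(outdir, "bootstrap.json", boot_payload, cfg_hash)

    age_payload = None
    if inf.age_control:
        age_payload = {}
        for group in groups:
            ds_res = regress_out_age(datasets[group])
            cv_age = run_cv(ds_res, config.cv)
            age_payload[group] = {"mean_accuracy": cv_age.mean_accuracy}
        _write(outdir, "age_control.json", {"groups": age_payload}, cfg_hash)

    return report(outdir)


def report(run_dir: str | Path) -> dict[str, Any]:
    """Aggregate stage artifacts into a single report; computes nothing new."""
    run_dir = Path(run_dir)
    echo_path = run_dir / "config_echo.json"
    if not echo_path.exists():
        raise FileNotFoundError(f"missing artifact: {echo_path}")
    echo = json.loads(echo_path.read_text())
    cfg_hash = echo["config_hash"]
    recomputed = config_hash(echo["config"])
    if recomputed != cfg_hash:
        raise ConfigurationError(
            f"provenance mismatch: config_echo hash {cfg_hash} != {recomputed}")
    rep: dict[str, Any] = {"config_hash": cfg_hash,
                           "seed": echo["config"]["seed"], "groups": {}}
    for gdir in sorted(p for p in run_dir.iterdir() if p.is_dir()):
        group = gdir.name
        section: dict[str, Any] = {}
        for name in ("permutation", "relevance"):
            path = gdir / f"{name}.json"
            if not path.exists():
                log.warning("report: %s missing for group %s", name, group)
                section[name] = None
                continue
            payload = json.loads(path.read_text())
            if payload.get("config_hash") != cfg_hash:
                raise ConfigurationError(
                    f"provenance mismatch in {path.name} for group {group}")
            payload.pop("null_accuracies", None)
            payload.pop("stable_edges", None)
            section[name] = payload
        if (gdir / "cv_result.json").exists():
            cv_payload = json.loads((gdir / "cv_result.json").read_text())
            accs = [f["accuracy"] for f in cv_payload["folds"]]
            section["mean_accuracy"] = float(np.mean(accs))
        rep["groups"][group] = section
    for name in ("group_comparison", "bootstrap", "age_control"):
        path = run_dir / f"{name}.json"
        if path.exists():
            payload = json.loads(path.read_text())
            if payload.get("config_hash") != cfg_hash:
                raise ConfigurationError(f"provenance mismatch in {path.name}")
            payload.pop("accuracies", None)
            rep[name] = payload
        else:
            log.warning("report: artifact %s.json absent", name)
            rep[name] = None
    (run_dir / "report.json").write_text(json.dumps(rep, indent=1,
                                                    default=_jsonify))
    (run_dir / "summary.txt").write_text(_summarize(rep))
    return rep


def _summarize(rep: dict[str, Any]) -> str:
    lines = [f"meddecode run report (config {rep['config_hash']}, "
             f"seed {rep['seed']})", ""]
    for group, sec in rep["groups"].items():
        acc = sec.get("mean_accuracy")
        lines.append(f"[{group}]")
        if acc is not None:
            lines.append(f"  mean CV accuracy: {100 * acc:.1f}%")
        perm = sec.get("permutation")
        if perm:
            lines.append(f"  permutation p = {perm['p_value']:.4g} "
                         f"(n_perm={perm['n_perm']}, null mean "
                         f"{100 * perm['null_mean']:.1f}%)")
        relv = sec.get("relevance")
        if relv:
            lines.append(f"  stable edges: {relv['n_stable_edges']} "
                         f"(hemisphere counts {relv['hemisphere_counts']})")
        lines.append("")
    gc = rep.get("group_comparison")
    if gc:
        lines.append(f"group comparison: U = {gc['mann_whitney_U']:.0f}, "
                     f"p = {gc['mann_whitney_p']:.3g}")
    boot = rep.get("bootstrap")
    if boot:
        lines.append(f"bootstrap ({boot['group']} -> "
                     f"{boot['target_n_subjects']} subjects): mean accuracy "
                     f"{100 * boot['mean_accuracy']:.1f}%")
    age = rep.get("age_control")
    if age:
        for g, v in age["groups"].items():
            lines.append(f"age-controlled accuracy [{g}]: "
                         f"{100 * v['mean_accuracy']:.1f}%")
    return "\n".join(lines) + "\n"
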