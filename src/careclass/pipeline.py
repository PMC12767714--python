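"""End-to-end orchestration from a config mapping or YAML file.

A run executes: load-or-simulate -> (optional) missingness injection and
chained imputation -> class-number selection -> measurement fit ->
structural fit -> equity table -> sensitivity refits, writing each stage's
artifact incrementally and a JSON manifest with checksums at the end.
The master seed is split into one independent stream per stage with
``numpy.random.SeedSequence(master_seed).spawn``, in the stage order above,
so a config plus seed pins every number in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .measurement import IndicatorMatrix, fit_measurement, summarize_classes
from .selection import select_structure, sensitivity_subsets, MATERNAL_CARE, CHILD_CARE
from .structural import fit_two_step, odds_ratio_table
from .equity import StratifiedOutcome, equity_table
from .prep import PreparedDataset, chained_impute, weighted_summaries
from .synthetic import (GeneratorConfig, published_profile_config, simulate,
                        inject_missing, to_unit_records, truth_frames,
                        INDICATOR_NAMES)

log = logging.getLogger("careclass")


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Exactly one of ``input_path`` (unit-record CSV) or ``simulation``
    (generator settings) must be given.
    """

    output_dir: str
    seed: int = 0
    input_path: str | None = None
    simulation: dict | None = None
    K_range: list[int] = field(default_factory=lambda: [1, 2, 3])
    M_range: list[int] = field(default_factory=lambda: [1, 2])
    n_starts: int = 8
    tol: float = 1e-8
    max_iter: int = 1000
    missing_rate: float = 0.0
    impute: bool = False
    imputation_cycles: int = 10
    imputation_m: int = 5
    equity_dimensions: dict | None = None    # name -> {by: covariate, order:, ordered:}
    bootstrap_B: int = 200
    run_selection: bool = True
    run_structural: bool = True
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation must be set")
        if not self.K_range or not self.M_range:
            raise ValueError("K_range and M_range must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    config: PipelineConfig
    seed: int
    artifacts: dict = field(default_factory=dict)   # name -> file path
    tables: dict = field(default_factory=dict)      # name -> DataFrame
    params: dict = field(default_factory=dict)      # name -> JSON-able payload


def _load_unit_records(path: str) -> tuple[IndicatorMatrix, pd.DataFrame]:
    df = pd.read_csv(path)
    ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
    ycols.sort(key=lambda c: int(c[1:]))
    values = df[ycols].to_numpy(dtype=float)
    names = INDICATOR_NAMES[:len(ycols)] if len(ycols) == len(INDICATOR_NAMES) else ycols
    mat = IndicatorMatrix(values=values, group_ids=df["country_id"].to_numpy(),
                          weights=df.get("weight", pd.Series(1.0, index=df.index)).to_numpy(),
                          indicator_names=list(names))
    covs = df.drop(columns=["country_id", "weight", *ycols], errors="ignore")
    return mat, covs


def _write_csv(df: pd.DataFrame, path: Path, report: RunReport, name: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    report.artifacts[name] = str(path)
    report.tables[name] = df


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all configured stages; see the module docstring for order.

    Every stage failure raises with the stage name; artifacts written before
    the failure remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, seed=config.seed)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in streams]

    def stage(name):
        log.info("stage: %s", name)

    # ---- data ----
    stage("data")
    indiv_covs = pd.DataFrame()
    if config.simulation is not None:
        sim = dict(config.simulation)
        if sim.pop("published_defaults", True):
            gen = published_profile_config(J=sim.pop("J", 29),
                                       n_per_group=sim.pop("n_per_group", 500),
                                       seed=stage_seed[0],
                                       unequal_sizes=sim.pop("unequal_sizes", False))
        else:
            gen = GeneratorConfig(seed=stage_seed[0], **sim)
        data, covs, truth = simulate(gen)
        indiv_covs = covs.individual
        _write_csv(to_unit_records(data, covs), out / "unit_records.csv", report, "data")
        gtruth, rtruth = truth_frames(truth)
        _write_csv(gtruth, out / "truth_groups.csv", report, "truth_groups")
        _write_csv(rtruth, out / "truth_records.csv", report, "truth_records")
        if config.missing_rate > 0:
            data = inject_missing(data, config.missing_rate, "MCAR", seed=stage_seed[0])
    else:
        data, indiv_covs = _load_unit_records(config.input_path)

    prepared = PreparedDataset(indicators=data,
                               individual_covariates=indiv_covs if len(indiv_covs.columns) else None)

    # ---- descriptives ----
    stage("descriptives")
    ind_tab, country_tab = weighted_summaries(prepared)
    _write_csv(ind_tab, out / "summary_indicators.csv", report, "summary_indicators")
    _write_csv(country_tab, out / "summary_countries.csv", report, "summary_countries")

    # ---- imputation ----
    if config.impute and np.isnan(data.values).any():
        stage("imputation")
        completed = chained_impute(prepared, cycles=config.imputation_cycles,
                                   m=config.imputation_m, seed=stage_seed[1])
        data = completed[0].indicators    # class models refit per dataset upstream if desired
        prepared = completed[0]

    # ---- selection ----
    stage("selection")
    if config.run_selection:
        table = select_structure(data, config.K_range, config.M_range,
                                 seed=stage_seed[2], n_starts=max(2, config.n_starts // 2),
                                 tol=config.tol, max_iter=config.max_iter)
        K, M = table.chosen
        _write_csv(table.to_frame(), out / "selection.csv", report, "selection")
    else:
        K, M = max(config.K_range), max(config.M_range)

    # ---- measurement ----
    stage("measurement")
    fit = fit_measurement(data, K=K, M=M, n_starts=config.n_starts,
                          tol=config.tol, max_iter=config.max_iter, seed=stage_seed[3])
    report.params["measurement"] = {
        "K": K, "M": M, "loglik": fit.loglik, "converged": fit.converged,
        "pi": fit.params.pi.tolist(), "tau": fit.params.tau.tolist(),
        "rho": fit.params.rho.tolist(),
    }
    (out / "measurement_params.json").write_text(
        json.dumps(report.params["measurement"], indent=1))
    report.artifacts["measurement_params"] = str(out / "measurement_params.json")
    summ = summarize_classes(fit.posteriors, data.weights, data.group_labels)
    _write_csv(summ["group_assignments"], out / "group_assignments.csv",
               report, "group_assignments")
    post = pd.DataFrame(fit.posteriors.indiv_post,
                        columns=[f"P_k{k}" for k in range(K)])
    post.insert(0, "record_id", np.arange(len(post)))
    post["map"] = fit.posteriors.map_indiv
    _write_csv(post, out / "individual_posteriors.csv", report, "individual_posteriors")

    # ---- structural ----
    if config.run_structural and len(indiv_covs.columns):
        stage("structural")
        Z2 = pd.get_dummies(indiv_covs, drop_first=True).astype(float)
        sp = fit_two_step(data, fit.params, Z1=None, Z2=Z2)
        _write_csv(odds_ratio_table(sp), out / "odds_ratios.csv", report, "odds_ratios")

    # ---- equity ----
    if config.equity_dimensions:
        stage("equity")
        outcome = fit.posteriors.indiv_post[:, 0]   # canonical optimal class
        strat = {}
        for dim, es in config.equity_dimensions.items():
            col = indiv_covs[es["by"]].to_numpy()
            strat[dim] = StratifiedOutcome.from_arrays(
                outcome=outcome, subgroup=col,
                country=np.asarray(data.group_labels)[data.group_index],
                weight=data.weights, order=es.get("order"),
                ordered=es.get("ordered", True), dimension=dim)
        eq = equity_table(strat, B=config.bootstrap_B, seed=stage_seed[4])
        _write_csv(eq, out / "equity.csv", report, "equity")

    # ---- sensitivity ----
    if config.run_sensitivity and data.H == len(INDICATOR_NAMES):
        stage("sensitivity")
        sens = sensitivity_subsets(
            data, {"maternal_care": MATERNAL_CARE, "child_care": CHILD_CARE},
            K=K, M=M, seed=stage_seed[5], n_starts=max(2, config.n_starts // 2))
        _write_csv(sens, out / "sensitivity.csv", report, "sensitivity")

    write_report(report, out)
    return report


def write_report(report: RunReport, out: Path) -> Path:
    """Write the JSON manifest listing every artifact with a sha256 checksum."""
    manifest = {
        "seed": report.seed,
        "version": __version__,
        "artifacts": {},
        "sections_absent": [],
    }
    for name in ("selection", "odds_ratios", "equity", "sensitivity"):
        if name not in report.artifacts:
            manifest["sections_absent"].append(name)
    for name, path in report.artifacts.items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        manifest["artifacts"][name] = {"path": str(path), "sha256": digest}
    mpath = Path(out) / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
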