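"""End-to-end analysis: NPARC baseline plus all four Bayesian model fits per protein.

For each complete protein the pipeline computes the NPARC F statistic and
p-value (effective degrees of freedom estimated dataset-wide first), the
Bayesian sigmoid and semi-parametric M0/M1 evidences and posterior model
probabilities, Delta-R^2 with the non-sigmoid flag, and sampler diagnostics.
Per-protein seeds are derived from the master seed and a CRC32 of the
protein id, so results are deterministic and independent of processing
order; partial results are checkpointed as JSON lines so an interrupted run
resumes without repeating completed proteins.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import checking, evidence
from .sigmoid import estimate_effective_dof, nparc_f_for_protein, nparc_pvalues
from .data import RESULT_COLUMNS, TPPDataset, read_long_table, write_results
from .models import ModelSpec
from .priors import (DEFAULT_SEMIPARAMETRIC_PRIORS, DEFAULT_SIGMOID_PRIORS,
                     PriorSpec)
from .sampling import ModelFit, SamplerSettings, sample_posterior

logger = logging.getLogger(__name__)

DEFAULT_PRIORS_BY_FAMILY = {"sigmoid": DEFAULT_SIGMOID_PRIORS,
                            "semiparametric": DEFAULT_SEMIPARAMETRIC_PRIORS}


@dataclass
class RunConfig:
    input_path: str | None = None
    input_format: str = "long"
    output_dir: str = "tppbayes_out"
    seed: int = 1
    n_walkers: int = 64
    n_warmup: int = 200
    n_draws: int = 250
    prior_prob_M0: float = evidence.DEFAULT_PRIOR_PROB_M0
    hit_threshold: float = evidence.DEFAULT_HIT_THRESHOLD
    delta_r2_threshold: float = checking.NON_SIGMOID_THRESHOLD
    nparc_alpha: float = 0.01
    nparc_trim_upper: float = 0.05
    gp_backend: str = "dense"
    protein_subset: list[str] | None = None
    families: tuple[str, ...] = ("sigmoid", "semiparametric")
    run_nparc: bool = True
    #: per-parameter prior overrides, e.g. {"sigma": {"family": "folded_normal",
    #: "params": [0.0, 0.1]}}; unlisted parameters keep the defaults
    priors: dict | None = None

    def __post_init__(self):
        if not (0 < self.hit_threshold <= 1 and 0 < self.prior_prob_M0 < 1):
            raise ValueError("thresholds must lie in (0, 1]")

    def prior_overrides(self) -> dict[str, PriorSpec]:
        if not self.priors:
            return {}
        return {name: PriorSpec(cfg["family"], tuple(cfg["params"]))
                for name, cfg in self.priors.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sampler_settings(self, seed: int) -> SamplerSettings:
        return SamplerSettings(n_walkers=self.n_walkers, n_warmup=self.n_warmup,
                               n_draws=self.n_draws, seed=seed,
                               gp_backend=self.gp_backend)


def protein_seed(master_seed: int, protein_id: str) -> int:
    """Deterministic per-protein seed below 2^31."""
    return (master_seed * 1000003 + zlib.crc32(protein_id.encode())) % (2**31)


def fit_protein_models(protein, config: RunConfig,
                       families=None) -> dict[tuple[str, str], ModelFit]:
    """Fit the requested family x hypothesis grid to one protein."""
    families = families or config.families
    seed = protein_seed(config.seed, protein.protein_id)
    overrides = config.prior_overrides()
    fits = {}
    for fi, family in enumerate(families):
        defaults = DEFAULT_PRIORS_BY_FAMILY[family]
        priors = {n: overrides.get(n, spec_default)
                  for n, spec_default in defaults.items()}
        for hi, hyp in enumerate(("M0", "M1")):
            spec = ModelSpec(family, hyp, priors=priors)
            fits[(family, hyp)] = sample_posterior(
                spec, protein, config.sampler_settings((seed + 104729 * (2 * fi + hi)) % (2**31)))
    return fits


def analyze_protein(protein, config: RunConfig) -> dict:
    """All Bayesian columns of one results row (NPARC columns added dataset-wide)."""
    row: dict = {"protein_id": protein.protein_id, "sampler_flagged": False,
                 "sampler_notes": ""}
    fits = fit_protein_models(protein, config)
    notes = []
    for family in config.families:
        m0, m1 = fits[(family, "M0")], fits[(family, "M1")]
        key = f"_{family}"
        if m0.flagged or m1.flagged:
            row["sampler_flagged"] = True
            notes.extend(f"{family}:{r}" for r in (m0.flag_reasons + m1.flag_reasons))
        try:
            logml0 = evidence.laplace_metropolis_logml(m0)
            logml1 = evidence.laplace_metropolis_logml(m1)
        except evidence.EvidenceError as exc:
            notes.append(f"{family}:evidence:{exc}")
            row.update({f"logml_M0{key}": np.nan, f"logml_M1{key}": np.nan,
                        f"log_bf10{key}": np.nan, f"posterior_prob_M1{key}": np.nan})
            row["sampler_flagged"] = True
            continue
        ev = evidence.posterior_model_prob(logml0, logml1, config.prior_prob_M0,
                                           P0=m0.spec.n_params, P1=m1.spec.n_params)
        row.update({f"logml_M0{key}": logml0, f"logml_M1{key}": logml1,
                    f"log_bf10{key}": ev.log_bayes_factor_10,
                    f"posterior_prob_M1{key}": ev.posterior_prob_M1})
    for family in config.families:
        pr = row.get(f"posterior_prob_M1_{family}", np.nan)
        row[f"hit_{family}"] = bool(np.isfinite(pr) and pr > config.hit_threshold
                                    and not row["sampler_flagged"])
    # predictive diagnostics on the condition-specific fits
    for family in config.families:
        try:
            loo = checking.psis_loo_elpd(
                checking.pointwise_loglik(fits[(family, "M1")], max_draws=500))
            row[f"elpd_loo_{family}"] = loo.elpd_loo
            row[f"elpd_loo_se_{family}"] = loo.se_elpd
            row[f"loo_n_high_k_{family}"] = loo.n_high_k
        except (ValueError, np.linalg.LinAlgError) as exc:
            notes.append(f"{family}:loo:{exc}")
            row[f"elpd_loo_{family}"] = np.nan
            row[f"elpd_loo_se_{family}"] = np.nan
            row[f"loo_n_high_k_{family}"] = -1
    ppc_family = ("semiparametric" if "semiparametric" in config.families
                  else config.families[0])
    try:
        ppc = checking.posterior_predictive_draws(
            fits[(ppc_family, "M1")], protein, n_rep=300,
            seed=protein_seed(config.seed, protein.protein_id + ":ppc"))
        row["ppc_coverage_50"] = ppc.coverage[0.5]
        row["ppc_coverage_95"] = ppc.coverage[0.95]
    except (ValueError, np.linalg.LinAlgError) as exc:
        notes.append(f"ppc:{exc}")
        row["ppc_coverage_50"] = np.nan
        row["ppc_coverage_95"] = np.nan
    if set(config.families) >= {"sigmoid", "semiparametric"}:
        try:
            r2_semi, r2_sig, dr2 = checking.delta_r2(
                protein, fits[("sigmoid", "M1")], fits[("semiparametric", "M1")])
            row.update({"r2_sigmoid": r2_sig, "r2_semiparametric": r2_semi,
                        "delta_r2": dr2,
                        "non_sigmoid_flag": checking.flag_non_sigmoid(
                            dr2, config.delta_r2_threshold)})
        except (ValueError, np.linalg.LinAlgError) as exc:
            notes.append(f"delta_r2:{exc}")
            row.update({"r2_sigmoid": np.nan, "r2_semiparametric": np.nan,
                        "delta_r2": np.nan, "non_sigmoid_flag": False})
    row["sampler_notes"] = ";".join(notes)
    return row


def nparc_table(dataset: TPPDataset, config: RunConfig,
                protein_ids: list[str]) -> pd.DataFrame:
    """NPARC F statistics, effective-dof p-values and BH adjustment."""
    Fs = []
    for pid in protein_ids:
        F, d1, d2 = nparc_f_for_protein(dataset.proteins[pid])
        Fs.append(F)
    Fs = np.asarray(Fs)
    try:
        d1e, d2e = estimate_effective_dof(Fs, trim_upper=config.nparc_trim_upper)
    except ValueError as exc:
        logger.warning("effective-dof estimation failed (%s); p-values are NaN", exc)
        return pd.DataFrame({"protein_id": protein_ids, "nparc_F": Fs,
                             "nparc_p": np.nan, "nparc_p_adj": np.nan})
    p, p_adj = nparc_pvalues(Fs, d1e, d2e)
    return pd.DataFrame({"protein_id": protein_ids, "nparc_F": Fs,
                         "nparc_p": p, "nparc_p_adj": p_adj})


def run_analysis(dataset_or_path, config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline; returns the ranked results table.

    The table has one row per analysable (complete) protein; excluded
    proteins are listed in the run log.  Rows are ranked by the
    semi-parametric posterior probability of a treatment effect, then by its
    log Bayes factor.  A JSONL checkpoint in the output directory lets a
    rerun skip already-analysed proteins.
    """
    if isinstance(dataset_or_path, TPPDataset):
        dataset = dataset_or_path
    else:
        dataset = read_long_table(dataset_or_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ckpt_path = outdir / "checkpoint.jsonl"

    pids = dataset.complete_proteins()
    if config.protein_subset:
        pids = [p for p in pids if p in set(config.protein_subset)]
    excluded = sorted(set(dataset.protein_ids) - set(pids))
    if excluded:
        logger.info("excluding %d proteins with missing cells: %s",
                    len(excluded), excluded[:10])

    done: dict[str, dict] = {}
    if ckpt_path.exists():
        with open(ckpt_path) as fh:
            for line in fh:
                rec = json.loads(line)
                done[rec["protein_id"]] = rec
    rows = []
    with open(ckpt_path, "a") as ck:
        for pid in pids:
            if pid in done:
                rows.append(done[pid])
                continue
            row = analyze_protein(dataset.proteins[pid], config)
            ck.write(json.dumps(row, default=float) + "\n")
            ck.flush()
            rows.append(row)
    results = pd.DataFrame(rows)
    if config.run_nparc:
        np_table = nparc_table(dataset, config, pids)
        results = np_table.merge(results, on="protein_id", how="right")
    sort_keys = [c for c in ("posterior_prob_M1_semiparametric",
                             "log_bf10_semiparametric",
                             "posterior_prob_M1_sigmoid") if c in results.columns]
    results = results.sort_values(sort_keys, ascending=False).reset_index(drop=True)
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results = results[cols]
    write_results(results, outdir / "results.tsv")
    meta = {"seed": config.seed, "n_proteins": len(pids),
            "n_excluded": len(excluded), "excluded": excluded,
            "settings": {k: v for k, v in config.__dict__.items()
                         if isinstance(v, (int, float, str, bool, list, tuple)) or v is None}}
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return results
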