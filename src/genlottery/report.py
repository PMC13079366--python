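"""Pipeline orchestration and the exact reporting conversions.

``run_pipeline`` runs simulate -> cohort -> the seven returns models (OLS,
sibling FE, DZ/MZ twin FE, MR, sibling-MR, FGWAS-reweighted MR) on both the
log and absolute earnings scales, then the diagnostics bundle (first-stage
F, balance tests), the summary-level MR suite, the UCI sensitivity curve,
the IV-OLS decomposition and the life-cycle profiles — all deterministically
from one config + seed.

Reporting helpers convert log points to percent and NOK to USD with the
half-up rounding used in published tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as decomp_mod
from . import fgwas as fgwas_mod
from . import lifecycle as lc_mod
from . import sensitivity as sens_mod
from . import summary_mr as smr
from .cohort import build_samples
from .config import SimConfig
from .estimators import (
    ModelSpec,
    balance_test,
    fit_family_fe,
    fit_ols,
    fit_sibling_mr,
    fit_tsls,
)
from .regress import EstimationError
from .simulate import simulate_population

MODEL_ORDER = ["ols", "sibling_fe", "twin_fe_dz", "twin_fe_mz", "mr", "sibling_mr", "fgwas_mr"]


def log_points_to_percent(b: float) -> float:
    """100*(exp(b)-1), rounded half-up to one decimal (0.077 -> 8.0)."""
    if not np.isfinite(b):
        raise ValueError("log-point value must be finite")
    pct = 100.0 * (np.exp(b) - 1.0)
    return float(Decimal(repr(float(pct))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def nok_to_usd(amount_nok: float, rate: float = 9.6) -> int:
    """NOK amount converted at USD/NOK ``rate``, rounded half-up to integer."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return int(Decimal(repr(float(amount_nok) / float(rate))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineRun:
    config: SimConfig
    seed: int
    config_hash: str
    estimates: pd.DataFrame
    diagnostics: dict
    summary_mr: dict
    sensitivity: object
    decomposition: object
    lifecycle: dict
    irr: dict
    log: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = self.config_hash[:8]
        self.estimates.to_csv(out / f"estimates_{h}.csv", index=False)
        with open(out / f"run_{h}.json", "w") as fh:
            json.dump({
                "seed": self.seed,
                "config": self.config.to_dict(),
                "diagnostics": _jsonable(self.diagnostics),
                "summary_mr": _jsonable(self.summary_mr),
                "irr": _jsonable(self.irr),
                "log": self.log,
            }, fh, indent=2, default=str)
        if self.sensitivity is not None:
            self.sensitivity.to_frame().to_csv(out / f"sensitivity_{h}.csv", index=False)
        if self.decomposition is not None:
            pd.DataFrame({
                "component": ["covariate", "margin", "residual", "gap"],
                "value": [self.decomposition.covariate_component,
                          self.decomposition.margin_component,
                          self.decomposition.residual_component,
                          self.decomposition.gap],
            }).to_csv(out / f"decomposition_{h}.csv", index=False)
        for name, prof in self.lifecycle.items():
            prof.to_csv(out / f"lifecycle_{name}_{h}.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: SimConfig) -> str:
    return hashlib.sha1(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()


def run_pipeline(config: SimConfig | str | Path, out_dir=None,
                 lifecycle_estimators=("ols", "mr"), n_boot: int = 200) -> PipelineRun:
    """Run the whole analysis from one configuration.

    Any stage failure raises an error naming the stage; results computed up
    to that point are written to ``out_dir`` first when one is given.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_file(config)
    log: list = []
    stage = "simulate"
    run = PipelineRun(config, config.seed, config_hash(config),
                      pd.DataFrame(), {}, {}, None, None, {}, {}, log)
    try:
        pop = simulate_population(config)
        log.append(f"simulate: n_offspring={pop.n_offspring}, n_families={pop.n_families}")

        stage = "cohort"
        samples, flow = build_samples(pop)
        run.diagnostics["flow"] = flow

        stage = "estimators"
        fgwas_ok = True
        try:
            w = fgwas_mod.within_family_snp_effects(samples["genotyped_sibling"])
            fgwas_mod.build_fgwas_piv(
                samples["genotyped_unrelated"], w,
                discovery_family_ids=samples["genotyped_sibling"].df["family_id"].unique(),
            )
            run.diagnostics["fgwas"] = {"n_snps": len(w.snp), "n_sibships": w.n_sibships}
        except EstimationError as e:
            fgwas_ok = False
            log.append(f"fgwas skipped: {e}")

        plans = [
            ("ols", "full", fit_ols, {}),
            ("sibling_fe", "sibling", fit_family_fe, {"fixed_effects": "family"}),
            ("twin_fe_dz", "twin_dz", fit_family_fe, {"fixed_effects": "family"}),
            ("twin_fe_mz", "twin_mz", fit_family_fe, {"fixed_effects": "family"}),
            ("mr", "genotyped", fit_tsls,
             {"instrument": "piv_std", "ci_method": "anderson_rubin"}),
            ("sibling_mr", "genotyped_sibling", fit_sibling_mr,
             {"instrument": "piv_std", "ci_method": "anderson_rubin"}),
            ("fgwas_mr", "genotyped_unrelated", fit_tsls,
             {"instrument": "piv_fgwas", "ci_method": "anderson_rubin"}),
        ]
        rows = []
        for model, samp_label, fitter, kw in plans:
            if model == "fgwas_mr" and not fgwas_ok:
                log.append("fgwas_mr: skipped (no FGWAS instrument)")
                continue
            sample = samples[samp_label]
            if sample.n == 0:
                log.append(f"{model}: empty sample {samp_label}")
                continue
            for outcome in ("log", "abs"):
                spec = ModelSpec(outcome=outcome, **kw)
                try:
                    res = fitter(sample, spec)
                except EstimationError as e:
                    log.append(f"{model}/{outcome}: {e}")
                    continue
                row = res.to_dict()
                row.update({"model": model, "sample": samp_label,
                            "seed": config.seed, "config_hash": run.config_hash})
                rows.append(row)
        run.estimates = pd.DataFrame(rows)

        stage = "diagnostics"
        gs = samples["genotyped"]
        bal_between, joint_between = balance_test(gs)
        bal_within, joint_within = balance_test(samples["genotyped_sibling"], within_family=True)
        run.diagnostics["balance_between"] = bal_between
        run.diagnostics["balance_joint_between"] = joint_between
        run.diagnostics["balance_within"] = bal_within
        run.diagnostics["balance_joint_within"] = joint_within

        stage = "summary_mr"
        summ = smr.per_snp_associations(gs)
        run.summary_mr = {
            "ivw": smr.ivw(summ).__dict__,
            "egger": smr.egger(summ).__dict__,
            "weighted_median": smr.weighted_median(summ, n_boot=n_boot, rng=config.seed + 1).__dict__,
            "weighted_mode": smr.mode_estimator(summ, n_boot=n_boot, rng=config.seed + 2).__dict__,
            "simple_mode": smr.mode_estimator(summ, weighted=False, n_boot=n_boot,
                                              rng=config.seed + 3).__dict__,
            "corge": smr.corge(summ).__dict__,
        }

        stage = "sensitivity"
        run.sensitivity = sens_mod.uci_sensitivity(
            gs, ModelSpec(outcome="abs", instrument="piv_std"), n_grid=41)

        stage = "decomposition"
        run.decomposition = decomp_mod.decompose_gap(gs, ModelSpec(outcome="log",
                                                                   instrument="piv_std"))

        stage = "lifecycle"
        for est in lifecycle_estimators:
            samp = samples["genotyped" if est == "mr" else "full"]
            ages = range(17, 53) if est == "mr" else range(17, 63)
            prof = lc_mod.age_specific_returns(samp, est, ages=ages)
            run.lifecycle[est] = prof
            try:
                irr = lc_mod.internal_rate_of_return(prof)
                run.irr[est] = {"irr": irr.irr, "profitable": irr.profitable,
                                "lifetime_return": lc_mod.lifetime_return(prof)}
            except EstimationError as e:
                log.append(f"irr[{est}]: {e}")
    except Exception as e:
        if out_dir is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    run.write(out_dir)
                except Exception:
                    pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    if out_dir is not None:
        run.write(out_dir)
    return run
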