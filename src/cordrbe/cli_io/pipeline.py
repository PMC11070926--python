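"""End-to-end pipeline: simulate -> actuarial -> fits -> RBE -> predict -> compare.

Each stage is timed and logged; any stage failure is re-raised with a
stage tag.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

import time
from pathlib import Path

from .. import reference
from ..actuarial import summarize_cohort
from ..dose_response import ED50Result, FiellerInterval, ed50_from_groups
from ..lq_bed import BED50Result, IdentifiabilityError, bed50, fit_lq_logistic, rbe_max
from ..rbe_stats import rbe_ratio
from ..synthetic_cohort import TrueResponseParams, simulate_table1
from ..track_models import (
    IonBeam,
    LEMParams,
    MKMParams,
    PhotonLQ,
    lem1_alpha_beta,
    mkm_alpha_beta,
    mkm_zstar,
    model_comparison,
    predict_rbe,
)
from .config import RunConfig
from .io import read_animal_table, write_animal_table, write_group_table, write_results

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _photon_ed50(photon_cfg: dict, n_fractions: int) -> ED50Result:
    v = photon_cfg["ed50_1fx" if n_fractions == 1 else "ed50_2fx"]
    s = photon_cfg["se_1fx" if n_fractions == 1 else "se_2fx"]
    return ED50Result(ed50=v, se=s, cl90=FiellerInterval(v - 1.645 * s, v + 1.645 * s))


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle into ``config.out_dir``.

    Returns the summary payload (also written to ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t_all = time.perf_counter()

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4)})
            return result
        return wrap

    # -- cohort ------------------------------------------------------------
    if config.animal_table:
        records = stage("read")(read_animal_table, config.animal_table)
    else:
        truth = {
            float(let): TrueResponseParams(**params)
            for let, params in config.truth.items()
        }
        records = stage("simulate")(simulate_table1, truth, config.seed)
        write_animal_table(out / "animals.csv", records)

    # -- actuarial ---------------------------------------------------------
    irradiated = [r for r in records if r.total_dose > 0]
    groups = stage("actuarial")(summarize_cohort, irradiated)
    write_group_table(out / "groups.csv", groups)

    # -- dose-response fits per (LET, schedule) ----------------------------
    photon_cfg = config.photon
    summary: dict[str, dict] = {}
    deviations = None
    lem_params = LEMParams(**{k: v for k, v in config.lem.items()
                              if k in ("r_min", "track_coeff", "track_exp", "nucleus_radius")})
    photon_lq = PhotonLQ(alpha_x=config.lem["alpha_x"], beta_x=config.lem["beta_x"],
                         d_t=config.lem["d_t"])
    mkm_params = MKMParams(**config.mkm)
    mkm_photon = PhotonLQ(alpha_x=config.mkm["alpha_0"], beta_x=config.mkm["beta_m"])

    measured_rbe = []
    predictions = []
    for let in sorted({g.let_value for g in groups}):
        per_let = [g for g in groups if g.let_value == let]
        entry: dict = {"let_value": let}
        for nfx in sorted({g.n_fractions for g in per_let}):
            sub = [g for g in per_let if g.n_fractions == nfx]
            res = stage(f"fit-dr let={let} nfx={nfx}")(
                ed50_from_groups, sub, config.level)
            photon = _photon_ed50(photon_cfg, nfx)
            rbe = stage(f"rbe let={let} nfx={nfx}")(
                rbe_ratio, photon, res, let, nfx, config.level)
            measured_rbe.append(rbe)
            entry[f"ed50_{nfx}fx"] = {
                "value": res.ed50, "se": res.se,
                "cl90": [res.cl90.low, res.cl90.high], "method": res.method,
            }
            entry[f"rbe_{nfx}fx"] = {"value": rbe.rbe, "se": rbe.se, "cl90": list(rbe.cl90)}

            # model predictions at the per-fraction ED50 dose
            d_frac = res.ed50 / nfx
            beam = IonBeam(let_value=let)
            a_lem, b_lem = lem1_alpha_beta(beam, photon_lq, lem_params)
            predictions.append(predict_rbe(a_lem, b_lem, photon_lq, d_frac, nfx,
                                           let_value=let, model_name="LEM1"))
            zstar = mkm_zstar(beam, mkm_params)
            a_mkm, b_mkm = mkm_alpha_beta(zstar, mkm_params)
            predictions.append(predict_rbe(a_mkm, b_mkm, mkm_photon, d_frac, nfx,
                                           let_value=let, model_name="mMKM"))

        # joint LQ fit across schedules
        try:
            lq = stage(f"fit-lq let={let}")(fit_lq_logistic, per_let)
            b50 = bed50(lq, config.level)
            photon_b50 = BED50Result(bed50=photon_cfg["bed50"], se=photon_cfg["bed50_se"],
                                     cl90=FiellerInterval(float("nan"), float("nan")))
            rmax = rbe_max(photon_b50, b50, config.level)
            entry["alpha_beta"] = {"value": lq.alpha_beta,
                                   "se": float(lq.cov[2, 2]) ** 0.5}
            entry["bed50"] = {"value": b50.bed50, "se": b50.se,
                              "cl90": [b50.cl90.low, b50.cl90.high]}
            entry["rbe_max"] = {"value": rmax.rbe_max, "se": rmax.se,
                                "cl90": list(rmax.cl90)}
        except PipelineError as exc:
            if not isinstance(exc.cause, IdentifiabilityError):
                raise
            entry["alpha_beta"] = {"error": str(exc.cause)}
        summary[f"let_{let:g}"] = entry

    # -- model comparison --------------------------------------------------
    deviations = stage("compare")(model_comparison, measured_rbe, predictions)
    deviations.to_csv(out / "deviations.csv", index=False)

    payload = {
        "seed": config.seed,
        "level": config.level,
        "summary": summary,
        "log": log + [{"stage": "total", "seconds": round(time.perf_counter() - t_all, 4)}],
    }
    write_results(out / "summary.json", payload, config.to_dict())
    return payload
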