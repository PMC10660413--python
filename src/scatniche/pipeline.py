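"""Config-driven end-to-end orchestration of the analysis stages.

Runs simulate -> QC filters -> diet -> diversity -> occurrence tests ->
hormone GLMs -> NDVI comparisons -> assay QC -> report on one output
directory, writing diff-able CSV/JSON artifacts and a run manifest with
config hash, seeds and stage outputs so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diet as diet_mod
from . import diversity as div_mod
from . import glm as glm_mod
from . import ndvi as ndvi_mod
from . import samples as io_mod
from . import stats as stats_mod
from . import synth
from .assay import accuracy_test, assay_cv, parallelism_test

__version__ = "0.1.0"

log = logging.getLogger("scatniche")

DEFAULT_DESIGN = [("East", 2015), ("West", 2015), ("East", 2020), ("West", 2020)]

DEFAULTS: dict = {
    "seed": 0,
    "iom_threshold_pct": 80.0,
    "design": [list(c) for c in DEFAULT_DESIGN],
    "simulation": {
        "multi_prey_rate": 0.102,
        "gamma_shape": 5.0,
        "iom_high_rate": 121.0 / 324.0,
        "ndvi_sd": 0.05,
    },
    "diversity": {"n_randomizations": 1000, "plateau_eps": 0.01, "plateau_run": 10},
    "contrasts": {"method": "single_step_mvn", "n_draws": 100000},
    "accuracy_band": [0.9, 1.1],
}


class PipelineError(RuntimeError):
    pass


def load_config(path=None) -> dict:
    """Merge a YAML config mapping over the printed defaults."""
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise PipelineError("config must be a YAML mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def sim_config(cfg: dict) -> synth.SimulationConfig:
    sim = cfg.get("simulation", {})
    return synth.SimulationConfig(
        seed=int(cfg.get("seed", 0)),
        multi_prey_rate=float(sim.get("multi_prey_rate", 0.102)),
        gamma_shape=float(sim.get("gamma_shape", 5.0)),
        iom_high_rate=float(sim.get("iom_high_rate", 121.0 / 324.0)),
        ndvi_sd=float(sim.get("ndvi_sd", 0.05)),
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    rng_algorithm: str
    started: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[str]):
        self.stages.append({"stage": name, "outputs": outputs})

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, out: Path) -> dict:
    sc = sim_config(cfg)
    ref = synth.default_prey_reference()
    samples = synth.gen_hormone_data(sc)
    rasters = synth.gen_ndvi_rasters(sc, seed=sc.seed + 1)
    std, ext = synth.gen_dilution_series(sc, parallel=True, seed=sc.seed + 2)
    replicates = synth.gen_replicate_matrix(sc, seed=sc.seed + 3)
    io_mod.write_samples(samples, out / "samples.csv")
    io_mod.write_prey_reference(ref, out / "prey_reference.csv")
    for year, r in rasters.items():
        ndvi_mod.write_ascii_grid(r, out / f"ndvi_{year}.asc")
    with open(out / "dilution_series.csv", "w") as fh:
        fh.write("series,dose,response_pct\n")
        for s in (std, ext):
            for d, r in zip(s.dose, s.response):
                fh.write(f"{s.kind},{d!r},{r!r}\n")
    with open(out / "assay_replicates.csv", "w") as fh:
        fh.write("plate,sample,rep1,rep2\n")
        for plate, rows in replicates.items():
            for i, reps in enumerate(rows):
                fh.write(f"{plate},{i},{reps[0]!r},{reps[1]!r}\n")
    log.info("simulate: %d scats, %d rasters (%s)", len(samples), len(rasters),
             synth.RNG_ALGORITHM)
    return {
        "samples": samples, "ref": ref, "rasters": rasters,
        "dilutions": (std, ext), "replicates": replicates,
    }


def stage_diet(samples, ref, cfg: dict, out: Path) -> dict:
    thr = float(cfg["iom_threshold_pct"])
    log.info("diet: digestibility correction Y = %.3f + %.3f X; IOM discard at >= %.1f%%",
             diet_mod.ACKERMAN_INTERCEPT, diet_mod.ACKERMAN_SLOPE, thr)
    identified, unidentified = io_mod.filter_prey_identified(samples)
    design = [tuple(c) for c in cfg["design"]]
    groups = io_mod.group_samples(identified, design)
    summaries = [diet_mod.summarize_group(g, ref) for g in groups]
    species = sorted({sp for s in summaries for sp in s.rfo_pct})
    with open(out / "diet_table1.csv", "w") as fh:
        fh.write("species,mean_body_weight_kg," + ",".join(
            f"{s.group_label}_rfo_pct,{s.group_label}_biomass_pct" for s in summaries
        ) + "\n")
        for sp in species:
            cells = []
            for s in summaries:
                cells.append(f"{diet_mod.round_half_up(s.rfo_pct.get(sp, 0.0))}")
                cells.append(f"{diet_mod.round_half_up(s.biomass_pct.get(sp, 0.0))}")
            fh.write(f"{sp},{ref.weight(sp)!r}," + ",".join(cells) + "\n")
    with open(out / "diet_table2.csv", "w") as fh:
        fh.write("size_class," + ",".join(s.group_label for s in summaries) + "\n")
        for cls in diet_mod.SIZE_CLASSES:
            fh.write(cls + "," + ",".join(
                f"{diet_mod.round_half_up(s.afo_pct[cls])}" for s in summaries
            ) + "\n")
    return {"groups": groups, "summaries": summaries,
            "identified": identified, "unidentified": unidentified}


def stage_diversity(groups, cfg: dict, out: Path) -> list[div_mod.RarefactionCurve]:
    d = cfg["diversity"]
    curves = []
    with open(out / "rarefaction.csv", "w") as fh:
        fh.write("group,t,mean_H,sd_H\n")
        for g in groups:
            curve = div_mod.rarefy(g, n_randomizations=int(d["n_randomizations"]),
                                   seed=int(cfg["seed"]))
            curves.append(curve)
            for t, mh, sh in zip(curve.t, curve.mean_H, curve.sd_H):
                fh.write(f"{g.label},{t},{mh!r},{sh!r}\n")
    plateaus = {
        c.group_label: div_mod.plateau_t(c, eps=float(d["plateau_eps"]),
                                         run=int(d["plateau_run"]))
        for c in curves
    }
    with open(out / "rarefaction_plateau.json", "w") as fh:
        json.dump(plateaus, fh, indent=2)
    return curves


def _afo_detection_counts(summaries):
    """size class -> per-group (yes, no) counts from AFO bookkeeping."""
    table = {}
    for cls in diet_mod.SIZE_CLASSES:
        table[cls] = [
            (s.class_counts[cls], s.n_samples - s.class_counts[cls]) for s in summaries
        ]
    return table


def stage_stats(summaries, out: Path) -> dict:
    """Occurrence-frequency tests: chi-square across groups, pairwise exact."""
    counts = _afo_detection_counts(summaries)
    labels = [s.group_label for s in summaries]
    results: dict = {}
    for cls, rows in counts.items():
        chi = stats_mod.chi_square_independence(rows)
        pairwise = {}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                fe = stats_mod.fisher_exact_2x2([rows[i], rows[j]])
                pairwise[f"{labels[i]} vs {labels[j]}"] = {
                    "odds_ratio": fe.statistic, "p": fe.p_value,
                }
        results[cls] = {
            "chi_square": {"statistic": chi.statistic, "df": chi.df, "p": chi.p_value},
            "pairwise_fisher": pairwise,
        }
    with open(out / "afo_tests.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results


def _buffer_ndvi(sample, rasters) -> float | None:
    raster = rasters.get(sample.year)
    if raster is None or sample.x is None or sample.y is None:
        return None
    zone = ndvi_mod.make_buffer((sample.x, sample.y))
    st = ndvi_mod.zonal_mean(raster, zone)
    return None if st.empty else st.mean_ndvi


def stage_hormones(samples, ref, rasters, cfg: dict, out: Path) -> dict:
    thr = float(cfg["iom_threshold_pct"])
    kept, discarded = io_mod.filter_iom(samples, thr)
    log.info("hormones: %d kept / %d discarded at IOM >= %.1f%%",
             len(kept), len(discarded), thr)

    def prey_size_of(s):
        # largest body-size class among the prey found in the scat
        order = {"large": 0, "medium": 1, "small": 2}
        classes = sorted((ref.size_class(sp) for sp in s.prey), key=order.get)
        return classes[0] if classes else None

    ndvi_of = {s.sample_id: _buffer_ndvi(s, rasters) for s in kept}
    results: dict = {}
    ctr = cfg["contrasts"]
    for resp in ("fgcm", "ft3m"):
        with_resp = [s for s in kept if getattr(s, resp) is not None]
        design_ay, y_ay = glm_mod.build_design(with_resp, resp, terms=("area_year",))
        fit_ay = glm_mod.fit_gamma_glm(design_ay, y_ay)
        prey_samples = [s for s in with_resp if s.prey]
        design_ps, y_ps = glm_mod.build_design(
            prey_samples, resp, terms=("prey_size",), prey_size_of=prey_size_of
        )
        fit_ps = glm_mod.fit_gamma_glm(design_ps, y_ps)
        null_design = glm_mod.GLMDesign(
            np.ones((len(y_ay), 1)), ("(Intercept)",), resp
        )
        fit_null = glm_mod.fit_gamma_glm(null_design, y_ay)
        lrt = glm_mod.likelihood_ratio_test(fit_ay, fit_null)
        contrasts = glm_mod.pairwise_contrasts(
            fit_ay, method=ctr["method"], n_draws=int(ctr["n_draws"]),
            seed=int(cfg["seed"]),
        )
        pairs_nd = [
            (getattr(s, resp), ndvi_of[s.sample_id])
            for s in with_resp if ndvi_of[s.sample_id] is not None
        ]
        if len(pairs_nd) >= 3:
            h = [p[0] for p in pairs_nd]
            nd = [p[1] for p in pairs_nd]
            ndvi_lm, ndvi_fit = glm_mod.hormone_vs_ndvi_lm(h, nd)
        else:
            ndvi_lm, ndvi_fit = None, None
        results[resp] = {
            "area_year": fit_ay.coefficient_table(),
            "prey_size": fit_ps.coefficient_table(),
            "dispersion": fit_ay.dispersion,
            "lrt_vs_null": {"f": lrt.statistic, "df": lrt.df, "p": lrt.p_value},
            "contrasts": [asdict(c) for c in contrasts],
            "ndvi_lm": None if ndvi_lm is None else {
                "slope": ndvi_fit.slope, "slope_t": ndvi_fit.t,
                "f": ndvi_lm.statistic, "df": ndvi_lm.df, "p": ndvi_lm.p_value,
            },
        }
        with open(out / f"glm_{resp}_table3.csv", "w") as fh:
            fh.write("model,term,estimate,se,t_value,p_value\n")
            for model, fit in (("area_year", fit_ay), ("prey_size", fit_ps)):
                for row in fit.coefficient_table():
                    fh.write(
                        f"{model},{row['term']},{row['estimate']!r},"
                        f"{row['se']!r},{row['t_value']!r},{row['p_value']!r}\n"
                    )
    with open(out / "hormone_results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    results["n_kept"] = len(kept)
    results["n_discarded"] = len(discarded)
    return results


def stage_ndvi(cfg: dict, out: Path) -> dict:
    sc = sim_config(cfg)
    cell_stats = synth.gen_zone_cell_stats(sc, seed=sc.seed + 4)
    years = sorted(cell_stats)
    spatial = {
        str(y): ndvi_mod.compare_zones_spatial(cell_stats[y]) for y in years
    }
    temporal = ndvi_mod.compare_zones_temporal(cell_stats[years[0]], cell_stats[years[1]])
    payload = {
        "spatial": {
            y: {
                "anova": {"f": r["anova"].statistic, "df": r["anova"].df,
                          "p": r["anova"].p_value},
                "pairwise": [
                    {"pair": t.effect_detail["pair"], "q": t.statistic, "p": t.p_value}
                    for t in r["pairwise"]
                ],
            }
            for y, r in spatial.items()
        },
        "temporal": {
            z: {"t": r.statistic, "df": r.df, "p": r.p_value}
            for z, r in temporal.items()
        },
    }
    with open(out / "ndvi_comparisons.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(out / "ndvi_cell_means.csv", "w") as fh:
        fh.write("zone_id,parent_zone,year,mean_ndvi,n_pixels\n")
        for y in years:
            for st in cell_stats[y]:
                fh.write(f"{st.zone_id},{st.parent_zone},{st.year},"
                         f"{st.mean_ndvi!r},{st.n_pixels}\n")
    return payload


def stage_qc(dilutions, replicates, cfg: dict, out: Path) -> dict:
    std, ext = dilutions
    par = parallelism_test(std, ext)
    rng = np.random.default_rng(int(cfg["seed"]) + 5)
    expected = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
    observed = 1.09 * expected * (1.0 + rng.normal(0.0, 0.01, expected.size))
    acc = accuracy_test(expected, observed, band=tuple(cfg["accuracy_band"]))
    intra, inter = assay_cv(replicates)
    verdict = {
        "parallelism": {"f": par.statistic, "df": list(par.df), "p": par.p_value,
                        "parallel": par.p_value > 0.05},
        "accuracy": {"slope": acc.slope, "ci": [acc.ci_low, acc.ci_high],
                     "passed": acc.passed},
        "cv": {"intra_pct": intra, "inter_pct": inter},
    }
    with open(out / "assay_qc.json", "w") as fh:
        json.dump(verdict, fh, indent=2)
    return verdict


def run_pipeline(config_path=None, out_dir="results", config: dict | None = None) -> RunManifest:
    """Execute all stages in dependency order; abort on first stage error."""
    cfg = config if config is not None else load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=int(cfg["seed"]),
        package_version=__version__,
        rng_algorithm=synth.RNG_ALGORITHM,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "simulate"
    try:
        data = stage_simulate(cfg, out)
        manifest.add(stage, ["samples.csv", "prey_reference.csv", "ndvi_2015.asc",
                             "ndvi_2020.asc", "dilution_series.csv",
                             "assay_replicates.csv"])
        stage = "diet"
        dres = stage_diet(data["samples"], data["ref"], cfg, out)
        manifest.add(stage, ["diet_table1.csv", "diet_table2.csv"])
        stage = "diversity"
        stage_diversity(dres["groups"], cfg, out)
        manifest.add(stage, ["rarefaction.csv", "rarefaction_plateau.json"])
        stage = "stats"
        stage_stats(dres["summaries"], out)
        manifest.add(stage, ["afo_tests.json"])
        stage = "hormones"
        stage_hormones(data["samples"], data["ref"], data["rasters"], cfg, out)
        manifest.add(stage, ["glm_fgcm_table3.csv", "glm_ft3m_table3.csv",
                             "hormone_results.json"])
        stage = "ndvi"
        stage_ndvi(cfg, out)
        manifest.add(stage, ["ndvi_comparisons.json", "ndvi_cell_means.csv"])
        stage = "qc"
        stage_qc(data["dilutions"], data["replicates"], cfg, out)
        manifest.add(stage, ["assay_qc.json"])
    except Exception as e:
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    manifest.write(out / "manifest.json")
    return manifest
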