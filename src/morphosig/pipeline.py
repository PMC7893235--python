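"""End-to-end analysis: the four socio-sexual signal predictions.

Given a landmark dataset (read from files or simulated), the pipeline runs

1. optional landmark-level retrodeformation (bilateral symmetrization of
   mildly sheared specimens) and semilandmark sliding;
2. reflection-augmented (or plain) generalized Procrustes alignment;
3. shape-on-size allometry: whole-skull R^2 and permutation p, per-module
   size slopes with pairwise ANCOVA, per-module CAC slopes with ANCOVA;
4. modularity: ML hypothesis comparison on the landmark congruence matrix
   (raw and allometry-corrected), the between/within merge rule, and the
   covariance ratio with a landmark-permutation test;
5. disparity: per-landmark / per-module Procrustes variance and covariate
   tests against growth rate and within-module correlation;
6. dimorphism: dip tests on leading residual shape components, whole-skull
   and per module (globally and separately aligned), with and without the
   smallest ('juvenile') specimens.

Every stochastic stage draws its seed deterministically from one root seed,
so a run is reproducible from its configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .align import (RetrodeformationError, gpa, symmetric_gpa,
                    symmetrize_retrodeform)
from .allometry import (ShapeAllometry, cac_slope_per_module,
                        compare_slopes_ancova, module_size_allometry)
from .data import SpecimenDataset, ValidationError
from .dimorphism import dimorphism_scan, exclude_juveniles
from .disparity import disparity_covariate_test, procrustes_variance
from .modularity import (CorrelationModularity, ModuleHypothesis,
                         congruence_matrix, covariance_ratio,
                         default_hypothesis_set, merge_modules)
from .semilandmarks import slide_semilandmarks


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full run (paths or a simulation preset)."""

    seed: int
    data_path: str | None = None
    scheme_path: str | None = None
    dialect: str = "long_table"
    hypotheses_path: str | None = None
    simulate_preset: str | None = None        # "paper_like" | "desk"
    n_specimens: int = 30
    n_partial: int = 14
    retrodeform: bool = False
    slide: bool = True
    reflection_augmented: bool = True
    juvenile_variant: bool = True
    n_perm: int = 999
    n_mc: int = 2000
    n_components: int = 8
    alpha: float = 0.05
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "seed" not in doc:
            raise ValidationError("configuration must set a seed")
        return cls(**doc)


def _seed_for(root: int, stage: str) -> int:
    import zlib
    h = np.random.SeedSequence([root, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def _load_dataset(config: RunConfig) -> SpecimenDataset:
    if config.data_path is not None:
        if config.scheme_path is None:
            raise ValidationError("scheme_path required with data_path")
        with open(config.scheme_path) as fh:
            scheme = msio.read_scheme(fh)
        with open(config.data_path) as fh:
            return msio.read_landmarks(fh, scheme, dialect=config.dialect)
    from .simulate import make_truth, paper_like_truth, simulate_dataset
    seed = _seed_for(config.seed, "simulate")
    if config.simulate_preset in (None, "paper_like"):
        truth = paper_like_truth(seed=seed)
    elif config.simulate_preset == "desk":
        truth = make_truth(seed=seed)
    else:
        raise ValidationError(f"unknown preset {config.simulate_preset!r}")
    ds, _ = simulate_dataset(truth, n_specimens=config.n_specimens,
                             n_partial=config.n_partial, seed=seed)
    return ds


def _load_hypotheses(config: RunConfig, scheme) -> list[ModuleHypothesis]:
    if config.hypotheses_path is None:
        return default_hypothesis_set(scheme)
    import yaml
    with open(config.hypotheses_path) as fh:
        doc = yaml.safe_load(fh)
    idx = scheme.index
    out = []
    for name, modules in doc.items():
        labels = [None] * scheme.k
        for mod, ids in modules.items():
            for lid in ids:
                labels[idx[lid]] = mod
        if any(l is None for l in labels):
            raise ValidationError(f"hypothesis {name!r} leaves landmarks "
                                  "unassigned")
        out.append(ModuleHypothesis(str(name), tuple(labels)))
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline; returns (and optionally writes) the report."""
    report: dict = {"seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    dataset = stage("load")(lambda: _load_dataset(config))
    scheme = dataset.scheme

    if config.retrodeform:
        def _retro():
            configs = []
            done = set()
            for cfg in dataset.configurations:
                if cfg.is_complete and scheme.pairs:
                    try:
                        configs.append(symmetrize_retrodeform(cfg))
                        done.add(cfg.specimen_id)
                        continue
                    except (RetrodeformationError, ValidationError):
                        pass
                configs.append(cfg)
            report["retrodeformed"] = sorted(done)
            return SpecimenDataset(scheme, configs, done)
        dataset = stage("retrodeform")(_retro)

    complete = stage("subset")(dataset.complete_subset)

    if config.slide and any(t != "fixed" for t in scheme.types):
        def _slide():
            slid, slog = slide_semilandmarks(complete)
            report["slide_energy"] = {
                "pre": slog["energy_pre"], "post": slog["energy_post"]}
            return slid
        complete = stage("slide")(_slide)

    def _align():
        if config.reflection_augmented and scheme.midline_indices.size >= 3:
            return symmetric_gpa(complete)
        return gpa(complete)
    aligned = stage("align")(_align)
    report["alignment"] = {
        "protocol": aligned.log.get("protocol", "gpa"),
        "iterations": aligned.log.get("iterations"),
        "n_specimens": aligned.n, "n_landmarks": aligned.k,
    }

    # ----- allometry --------------------------------------------------------
    def _allometry():
        res = ShapeAllometry(aligned).fit(
            n_perm=config.n_perm, seed=_seed_for(config.seed, "allometry"))
        from .align import centroid_size
        size_tab = module_size_allometry(complete)
        x = aligned.log_sizes()
        xs, ys, gs = [], [], []
        for mod in scheme.module_names:
            idx = scheme.module_indices(mod)
            mod_cs = np.log([centroid_size(c.coords[idx])
                             for c in complete.configurations])
            xs.append(x)
            ys.append(mod_cs)
            gs.append(np.repeat(mod, x.size))
        size_ancova = compare_slopes_ancova(
            np.concatenate(xs), np.concatenate(ys), np.concatenate(gs))
        cac_tab, cac_scores = cac_slope_per_module(aligned)
        mods = list(scheme.module_names)
        cx = np.concatenate([x] * len(mods))
        cy = np.concatenate([cac_scores[m] for m in mods])
        cg = np.concatenate([np.repeat(m, x.size) for m in mods])
        cac_ancova = compare_slopes_ancova(cx, cy, cg)
        return res, size_tab, size_ancova, cac_tab, cac_ancova
    allo, size_tab, size_ancova, cac_tab, cac_ancova = stage("allometry")(_allometry)
    corrected = allo.corrected()
    report["allometry"] = {
        "r_squared": allo.r_squared, "p": allo.p_value,
        "whole_skull_cac_slope": allo.cac_slope,
        "module_size_slopes": size_tab["slope"].to_dict(),
        "size_slope_ancova": size_ancova.to_dict(orient="records"),
        "module_cac_slopes": cac_tab["slope"].to_dict(),
        "cac_slope_ancova": cac_ancova.to_dict(orient="records"),
    }

    # ----- modularity -------------------------------------------------------
    def _modularity():
        hyps = _load_hypotheses(config, scheme)
        out = {}
        for tag, data in (("raw", aligned), ("corrected", corrected)):
            R = congruence_matrix(data, scheme.landmark_ids)
            fit = CorrelationModularity(R, hyps, aligned.n).fit()
            merged = merge_modules(fit)
            cr, crp, cr_pairs = covariance_ratio(
                data, list(scheme.modules), n_perm=config.n_perm,
                seed=_seed_for(config.seed, f"cr-{tag}"))
            out[tag] = {
                "fit": fit, "merged": merged, "cr": cr, "cr_p": crp,
                "cr_pairs": cr_pairs,
            }
        return out
    modularity = stage("modularity")(_modularity)
    report["modularity"] = {
        tag: {
            "best_model": v["fit"].best_model,
            "best_n_modules": int(v["fit"].table.iloc[0]["n_modules"]),
            "merged_n_modules": v["merged"].n_modules,
            "CR": v["cr"], "CR_p": v["cr_p"],
            "aicc_weights": v["fit"].table["weight"].round(6).to_dict(),
        }
        for tag, v in modularity.items()
    }

    # ----- disparity --------------------------------------------------------
    def _disparity():
        out = {}
        for tag, data in (("raw", aligned), ("corrected", corrected)):
            out[tag] = procrustes_variance(data, variant=tag)
        mods = list(out["corrected"].per_module.index)
        disp = out["corrected"].per_module["normalized"].to_numpy()
        growth = size_tab.loc[mods, "slope"].to_numpy()
        rho_w = _within_rho(modularity["corrected"]["fit"], mods)
        cov_tests = {
            "growth_rate": disparity_covariate_test(disp, growth),
            "within_correlation": disparity_covariate_test(disp, rho_w),
        }
        return out, cov_tests
    disparity_tabs, disp_tests = stage("disparity")(_disparity)
    report["disparity"] = {
        "normalized": {
            tag: t.per_module["normalized"].to_dict()
            for tag, t in disparity_tabs.items()},
        "covariate_tests": {kname: {"slope": v[0], "r": v[1], "p": v[2]}
                            for kname, v in disp_tests.items()},
    }

    # ----- dimorphism -------------------------------------------------------
    def _dimorphism():
        seed = _seed_for(config.seed, "dip")
        scans = []
        subsets = {"all": np.arange(aligned.n)}
        if config.juvenile_variant:
            adults, juv = exclude_juveniles(aligned.log_sizes())
            report["juveniles"] = [aligned.specimen_ids[i]
                                   for i in np.flatnonzero(juv)]
            # only a minority at the small end counts as a juvenile cluster
            if juv.any() and adults.size >= max(8, aligned.n // 2):
                subsets["adults"] = adults
        for subset_name, rows in subsets.items():
            score_sets = {}
            sub = aligned.coords[rows]
            sub_sizes = aligned.log_sizes()[rows]
            whole = ShapeAllometry(sub, log_sizes=sub_sizes).fit(n_perm=1)
            score_sets["whole_skull"] = whole.residual_component_scores()
            for mod in scheme.module_names:
                idx = scheme.module_indices(mod)
                mres = ShapeAllometry(sub[:, idx, :],
                                      log_sizes=sub_sizes).fit(n_perm=1)
                score_sets[f"{mod}.global"] = mres.residual_component_scores()
            # separately aligned modules, partial specimens included
            for mod in scheme.module_names:
                try:
                    msub = dataset.module_subset(mod)
                except ValidationError:
                    continue
                mal = gpa(msub)
                if subset_name == "adults":
                    keep, _ = exclude_juveniles(mal.log_sizes())
                    if keep.size < 8:
                        continue
                    mal = _subset_aligned(mal, keep)
                sres = ShapeAllometry(mal).fit(n_perm=1)
                score_sets[f"{mod}.separate"] = sres.residual_component_scores()
            scan = dimorphism_scan(score_sets,
                                   n_components=config.n_components,
                                   n_mc=config.n_mc, seed=seed,
                                   alpha=config.alpha, subset=subset_name)
            scans.append(scan)
        return pd.concat(scans, ignore_index=True)
    dip_table = stage("dimorphism")(_dimorphism)
    report["dimorphism"] = {
        "n_tests": int(len(dip_table)),
        "n_flagged": int(dip_table["flag"].sum()),
        "min_p": float(dip_table["p"].min()),
        "expected_false_flags": float(len(dip_table) * config.alpha),
    }

    report["predictions"] = _summarize_predictions(report)

    if config.out_dir is not None:
        _write_outputs(Path(config.out_dir), report, aligned, size_tab,
                       cac_tab, disparity_tabs, dip_table, modularity)
    return report


def _subset_aligned(aligned, rows):
    from .align import AlignedDataset
    return AlignedDataset(
        scheme=aligned.scheme, coords=aligned.coords[rows],
        centroid_sizes=aligned.centroid_sizes[rows],
        consensus=aligned.consensus,
        specimen_ids=[aligned.specimen_ids[i] for i in rows],
        log=dict(aligned.log), augmented=True)


def _within_rho(fit, modules):
    name = fit.best_model
    hyp = fit.best_hypothesis
    alt = f"{hyp.name}.separate"
    rho = fit.rho.get(alt, fit.rho[name])
    out = []
    for m in modules:
        key = f"within.{m}"
        out.append(rho.get(key, np.nan))
    vals = np.asarray(out, float)
    if np.isnan(vals).any():
        # best model may use pooled labels; fall back to the anatomical fit
        for cand, r in fit.rho.items():
            got = [r.get(f"within.{m}") for m in modules]
            if all(g is not None for g in got):
                return np.asarray(got, float)
    return vals


def _summarize_predictions(report: dict) -> dict:
    size_slopes = report["allometry"]["module_size_slopes"]
    cac_slopes = {m: v for m, v in
                  report["allometry"]["module_cac_slopes"].items()
                  if m != "whole"}
    disp = report["disparity"]["normalized"]["corrected"]
    top_size = max(size_slopes, key=size_slopes.get)
    top_cac = max(cac_slopes, key=cac_slopes.get)
    top_disp = max(disp, key=disp.get)
    mod = report["modularity"]["corrected"]
    return {
        "modularity": {
            "supported": bool(mod["merged_n_modules"] >= 2
                              and mod["CR"] < 1.0 and mod["CR_p"] <= 0.05),
            "merged_modules": mod["merged_n_modules"],
            "CR": mod["CR"], "CR_p": mod["CR_p"],
        },
        "ontogenetic_allometry": {
            "top_size_slope_module": top_size,
            "top_cac_slope_module": top_cac,
            "size_slope": size_slopes[top_size],
            "cac_slope": cac_slopes[top_cac],
        },
        "variance": {"top_disparity_module": top_disp,
                     "normalized_disparity": disp[top_disp]},
        "dimorphism": {
            "any_flag": bool(report["dimorphism"]["n_flagged"] > 0),
            "min_p": report["dimorphism"]["min_p"],
        },
    }


def _write_outputs(out: Path, report, aligned, size_tab, cac_tab,
                   disparity_tabs, dip_table, modularity) -> None:
    out.mkdir(parents=True, exist_ok=True)
    size_tab.to_csv(out / "module_size_slopes.csv")
    cac_tab.to_csv(out / "module_cac_slopes.csv")
    dip_table.to_csv(out / "dip_scan.csv", index=False)
    for tag, t in disparity_tabs.items():
        t.per_module.to_csv(out / f"disparity_{tag}.csv")
        t.per_landmark.to_csv(out / f"disparity_landmarks_{tag}.csv")
    for tag, v in modularity.items():
        v["fit"].table.to_csv(out / f"modularity_{tag}.csv")
        v["cr_pairs"].to_csv(out / f"cr_pairs_{tag}.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(report))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def render_summary(report: dict) -> str:
    p = report["predictions"]
    lines = [
        "Four-prediction summary",
        "=" * 60,
        "1. Modularity:",
        f"   merged module count: {p['modularity']['merged_modules']}",
        f"   CR (corrected): {p['modularity']['CR']:.3f}"
        f"  (p = {p['modularity']['CR_p']:.4f})",
        f"   supported: {p['modularity']['supported']}",
        "2. Ontogenetic size/shape change:",
        f"   steepest size slope:  {p['ontogenetic_allometry']['top_size_slope_module']}"
        f"  ({p['ontogenetic_allometry']['size_slope']:.3f})",
        f"   steepest CAC slope:   {p['ontogenetic_allometry']['top_cac_slope_module']}"
        f"  ({p['ontogenetic_allometry']['cac_slope']:.4f})",
        "3. Morphological variance:",
        f"   highest normalized disparity: {p['variance']['top_disparity_module']}"
        f"  ({p['variance']['normalized_disparity']:.3e})",
        "4. Sexual dimorphism:",
        f"   dip-test flags: {report['dimorphism']['n_flagged']}"
        f" of {report['dimorphism']['n_tests']}"
        f"  (expected false flags {report['dimorphism']['expected_false_flags']:.1f})",
        f"   smallest p: {p['dimorphism']['min_p']:.4f}",
    ]
    return "\n".join(lines)
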