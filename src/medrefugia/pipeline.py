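"""Pipeline orchestration: configuration, stage ordering, manifests.

Stages run in dependency order::

    simulate -> popgen, delimit          (molecular arm)
    simulate -> climate -> enm -> refugia (niche arm)

Every run is driven by a single root seed; stages derive named substreams
from it so they can be rerun independently and reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climate as climate_mod, delimit as delimit_mod
from . import enm as enm_mod, popgen as popgen_mod, refugia as refugia_mod
from . import synthdata
from .rasters import Raster, write_ascii_grid

__all__ = ["PipelineConfig", "run_pipeline", "run_enm_recovery", "jaccard",
           "derive_seed"]


def derive_seed(root_seed: int, stream: str) -> int:
    """Deterministic named substream seed below 2^31."""
    h = 2166136261
    for ch in f"{root_seed}:{stream}":
        h = (h ^ ord(ch)) * 16777619 % (2 ** 31)
    return h


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the study's defaults.

    Unknown keys are rejected by :meth:`from_dict` so typos cannot
    silently fall back to defaults.
    """

    outdir: str = "medrefugia_run"
    seed: int = 0
    # synthetic data
    n_samples: int = 60
    seq_length: int = 1016
    theta: float = 6.0
    n_lineages: int = 4
    n_localities: int = 15
    ibd_scale: float = 300.0
    mixing_fraction: float = 0.0
    grid_shape: tuple[int, int] = (60, 60)
    n_gcms: int = 4
    gcm_noise_sd: float = 0.5
    n_occurrences: int = 150
    # popgen
    grid_spacing_km: float = 100.0
    grid_m: int = 5
    grid_B: int = 1000
    n_perm: int = 999
    n_neutrality_sims: int = 1000
    # delimit
    connection_confidences: tuple[float, ...] = (0.95, 0.99)
    # climate / enm
    variance_target: float = 0.99
    buffer_km: float = 350.0
    thin_min_km: float = 50.0
    n_subsets: int = 3
    n_boot_reps: int = 10
    reg_multiplier: float = 1.0
    partial_roc_E: float = 0.01
    partial_roc_boot: int = 1000
    mop_alpha: float = 0.1
    # refugia
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    adjacency: str = "queen"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "fractions", "connection_confidences"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def sim_config(self) -> synthdata.SimConfig:
        return synthdata.SimConfig(
            seed=derive_seed(self.seed, "simulate"),
            n_samples=self.n_samples, seq_length=self.seq_length,
            theta=self.theta, n_lineages=self.n_lineages,
            n_localities=self.n_localities, ibd_scale=self.ibd_scale,
            mixing_fraction=self.mixing_fraction,
            grid_shape=self.grid_shape, n_gcms=self.n_gcms,
            gcm_noise_sd=self.gcm_noise_sd)


def jaccard(a: Raster | np.ndarray, b: Raster | np.ndarray) -> float:
    """Jaccard overlap of the suitable (==1) cells of two binary maps."""
    va = a.values if isinstance(a, Raster) else np.asarray(a)
    vb = b.values if isinstance(b, Raster) else np.asarray(b)
    pa = va == 1
    pb = vb == 1
    union = (pa | pb).sum()
    if union == 0:
        return float("nan")
    return float((pa & pb).sum() / union)


# ---------------------------------------------------------------------------
# niche-arm recovery workflow


def run_enm_recovery(cfg: PipelineConfig,
                     suite: synthdata.ClimateSuite | None = None,
                     truth: synthdata.SyntheticTruth | None = None,
                     occ: enm_mod.OccurrenceSet | None = None) -> dict:
    """Full niche arm on synthetic truth: climate -> ENM -> refugia.

    Fits one maxent ensemble per GCM on present-day conditions inside the
    buffered calibration region, projects to every slice with the
    current-conditions PCA enforced, aggregates
    (median-of-bootstrap-replicates then median-of-subsets), binarizes by
    minimum training presence over all occurrences, removes strictly
    extrapolative suitable cells (MOP), and delimits refugia by M1/M2 at
    each stringency. Returns suitability/binary maps, scenarios, and
    Jaccard overlap against the true refugia.
    """
    sim = cfg.sim_config()
    if suite is None:
        suite, truth = synthdata.simulate_climate_suite(sim)
    if occ is None:
        occ = synthdata.sample_occurrences(
            truth.true_suitability["present"], cfg.n_occurrences,
            seed=derive_seed(cfg.seed, "occurrences"))
    grid = suite.get(suite.gcms[0], "present").grid
    region = enm_mod.build_calibration_region(occ, grid,
                                              buffer_km=cfg.buffer_km)
    mask_flat = np.isfinite(region.mask.values).ravel()
    subsets = enm_mod.thin_occurrences(
        occ, min_km=cfg.thin_min_km, n_replicates=cfg.n_subsets,
        seed=derive_seed(cfg.seed, "thin"))
    binary: dict[tuple[str, str], Raster] = {}
    suits: dict[tuple[str, str], Raster] = {}
    mops: dict[tuple[str, str], enm_mod.MopMap] = {}
    for gcm in suite.gcms:
        bio_by_slice = {sl: climate_mod.compute_bioclim(suite.get(gcm, sl))
                        for sl in suite.slices}
        pca = climate_mod.fit_env_pca(bio_by_slice["present"],
                                      region_mask=mask_flat,
                                      variance_target=cfg.variance_target)
        scores = {sl: climate_mod.project_env(pca, bio_by_slice[sl])
                  for sl in suite.slices}
        pres_scores = scores["present"]
        k = pres_scores.shape[0]
        flat_scores = {sl: scores[sl].reshape(k, -1).T
                       for sl in suite.slices}
        bg = flat_scores["present"][mask_flat]
        models_per_subset = []
        for si, sub in enumerate(subsets):
            pres = _scores_at_points(pres_scores, grid, sub.latlon())
            models = enm_mod.fit_maxent(
                pres, bg, reg_multiplier=cfg.reg_multiplier,
                n_boot_reps=cfg.n_boot_reps,
                seed=derive_seed(cfg.seed, f"maxent:{gcm}:{si}"))
            models_per_subset.append(models)
        for sl in suite.slices:
            agg = enm_mod.predict_and_aggregate(models_per_subset,
                                                flat_scores[sl],
                                                scale=float(len(bg)))
            suits[(gcm, sl)] = grid.copy_with(agg.reshape(grid.shape))
        # the minimum-training-presence threshold comes from the training
        # (present-day) surface at all occurrences and is applied to every
        # temporal projection of that model
        _, tau = enm_mod.mtp_binarize(suits[(gcm, "present")], occ)
        for sl in suite.slices:
            suit = suits[(gcm, sl)]
            vals = np.where(np.isfinite(suit.values),
                            (suit.values >= tau).astype(float), np.nan)
            bin_map = suit.copy_with(vals)
            mop, masked = enm_mod.mop_mask(bg, flat_scores[sl],
                                           alpha=cfg.mop_alpha, binary=bin_map)
            mops[(gcm, sl)] = mop
            binary[(gcm, sl)] = masked
    ens = refugia_mod.BinaryEnsemble(maps=binary)
    scen = {m: refugia_mod.refugia_sweep(ens, m, fractions=cfg.fractions,
                                         adjacency=cfg.adjacency)
            for m in ("M1", "M2")}
    jac = {m: {s.fraction: jaccard(s.result, truth.true_refugia)
               for s in scen[m]} for m in scen}
    return {"suite": suite, "truth": truth, "occurrences": occ,
            "region": region, "suitability": suits, "binary": binary,
            "mop": mops, "ensemble": ens, "scenarios": scen, "jaccard": jac}


def _scores_at_points(score_stack: np.ndarray, grid: Raster,
                      latlon: np.ndarray) -> np.ndarray:
    out = []
    for lat, lon in latlon:
        r, c = grid.cell_of(lat, lon)
        out.append(score_stack[:, r, c])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# molecular-arm workflow


def run_molecular(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = cfg.sim_config()
    aln, truth = synthdata.simulate_geo_dataset(sim)
    artifacts = synthdata.write_geo_dataset(aln, truth, outdir, sim)
    haps = popgen_mod.collapse_haplotypes(aln)
    summary = popgen_mod.alignment_summary(aln)
    rows = [{"scope": "all", "n": summary.n, "L_eff": summary.L_eff,
             "S": summary.S, "H": summary.H, "Hd": summary.Hd,
             "pi": summary.pi, "kbar": summary.kbar}]
    lineages = sorted({s.lineage for s in aln.samples if s.lineage})
    for lin in lineages:
        sub = popgen_mod.GeoAlignment(
            [s for s in aln.samples if s.lineage == lin], aln.L)
        if len(sub) < 3:
            continue
        st = popgen_mod.alignment_summary(sub)
        row = {"scope": lin, "n": st.n, "L_eff": st.L_eff, "S": st.S,
               "H": st.H, "Hd": st.Hd, "pi": st.pi, "kbar": st.kbar}
        if st.S >= 1:
            row["Fs"] = popgen_mod.fu_fs(st)
            row["R2"] = popgen_mod.r2_stat(st)
        rows.append(row)
    stats = pd.DataFrame(rows)
    stats.to_csv(outdir / "summary_stats.csv", index=False)
    # Mantel on locality matrices
    mantel = None
    gdm, edm = popgen_mod.locality_matrices(aln)
    if len(gdm.labels) >= 5:
        mantel = popgen_mod.mantel_ibd(gdm, edm, n_perm=cfg.n_perm,
                                       seed=derive_seed(cfg.seed, "mantel"))
    # diversity grid
    dg = popgen_mod.diversity_grid(aln, spacing_km=cfg.grid_spacing_km,
                                   m=cfg.grid_m, B=cfg.grid_B,
                                   seed=derive_seed(cfg.seed, "divgrid"))
    dg.points.to_csv(outdir / "diversity_grid.csv", index=False)
    # delimitation
    limits = {c: delimit_mod.connection_limit(aln.L, c)
              for c in cfg.connection_confidences}
    networks = {c: delimit_mod.parsimony_networks(haps, lim)
                for c, lim in limits.items()}
    net_rows = [{"confidence": c, "max_steps": limits[c].max_steps,
                 "n_networks": len(networks[c].components)}
                for c in limits]
    pd.DataFrame(net_rows).to_csv(outdir / "parsimony_networks.csv",
                                  index=False)
    return {"alignment": aln, "truth": truth, "haplotypes": haps,
            "summary": stats, "mantel": mantel, "diversity_grid": dg,
            "limits": limits, "networks": networks,
            "artifacts": artifacts}


ALL_STAGES = ("simulate", "popgen", "delimit", "climate", "enm", "refugia")


def run_pipeline(cfg: PipelineConfig,
                 stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in dependency order; returns results and
    writes a manifest echoing the resolved configuration and seeds."""
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    need_molecular = {"popgen", "delimit"} & set(stages)
    need_niche = {"climate", "enm", "refugia"} & set(stages)
    if need_molecular and "simulate" not in stages:
        raise ValueError("stage 'simulate' must run before popgen/delimit")
    if need_niche and "simulate" not in stages:
        raise ValueError("stage 'simulate' must run before the niche arm")
    if "refugia" in stages and "enm" not in stages:
        raise ValueError("stage 'enm' must run before 'refugia'")
    if "enm" in stages and "climate" not in stages:
        raise ValueError("stage 'climate' must run before 'enm'")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {}
    timing: dict[str, float] = {}
    if need_molecular:
        t = time.time()
        results["molecular"] = run_molecular(cfg, outdir)
        timing["molecular"] = time.time() - t
    if need_niche:
        t = time.time()
        results["niche"] = run_enm_recovery(cfg)
        timing["niche"] = time.time() - t
        for (gcm, sl), r in results["niche"]["binary"].items():
            write_ascii_grid(r, outdir / f"binary_{gcm}_{sl}.asc")
        for m, scens in results["niche"]["scenarios"].items():
            for s in scens:
                write_ascii_grid(
                    s.result, outdir / f"refugia_{m}_k{s.k}.asc")
                s.components.to_csv(
                    outdir / f"refugia_{m}_k{s.k}_components.csv",
                    index=False)
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": list(stages),
        "timing_s": timing,
        "total_s": time.time() - t0,
    }
    if "niche" in results:
        manifest["jaccard"] = {
            m: {str(k): v for k, v in d.items()}
            for m, d in results["niche"]["jaccard"].items()}
    if results.get("molecular", {}).get("mantel"):
        mr = results["molecular"]["mantel"]
        manifest["mantel"] = {"r": mr.r, "p": mr.p, "n_perm": mr.n_perm}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
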