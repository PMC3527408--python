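"""Experiment orchestration: simulate -> invert -> evaluate over a grid.

One *cell* is a (placement, correlation regime, SNR, bilateral flag)
combination; each cell runs ``n_simulations`` independent simulations,
inverts each with every requested scheme and scores SAI/TAI.  Cells are
written as they complete and skipped on re-run, so an interrupted
experiment resumes to the identical final summary.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .evaluation import (compute_sai, compute_tai, default_search_sizes,
                         find_local_maxima)
from .geometry_forward import (build_synthetic_head, compute_leadfield,
                               green_smoother, select_patch_centers)
from .priors import msp_library
from .reduction import reduce_model, spatial_projector, temporal_projector
from .schemes import invert
from .simulator import SimulationSpec, select_dipole_locations, simulate

logger = logging.getLogger("megbayes")

__all__ = ["prepare_assets", "run_cell", "run_experiment", "write_report"]

_PLACEMENT_NDIP = {"single": 1, "symmetric_pair": 2, "asymmetric_pair": 2,
                   "random_triple": 3}


def prepare_assets(config: ExperimentConfig):
    """Head, leadfield, projector, patch libraries and candidate locations."""
    h = config.head
    mesh, sensors = build_synthetic_head(
        n_vertices=h.n_vertices, cortex_radius_mm=h.cortex_radius_mm,
        conductor_radius_mm=h.conductor_radius_mm, n_sensors=h.n_sensors,
        seed=config.seed, wrinkle_amp_mm=h.wrinkle_amp_mm,
        wrinkle_wavelength_mm=h.wrinkle_wavelength_mm)
    L = compute_leadfield(mesh, sensors)
    centers = select_patch_centers(mesh, config.library.p_per_hemisphere,
                                   seed=config.seed + 1)
    G = green_smoother(mesh, config.library.smoothness, columns=centers)
    U = spatial_projector(L)
    locations = select_dipole_locations(
        L, centers, n_locations=min(config.grid.n_locations, len(centers)),
        n_candidate_sets=config.grid.n_candidate_sets, seed=config.seed + 2)
    return {"mesh": mesh, "sensors": sensors, "L": L, "centers": centers,
            "G": G, "U": U, "locations": locations}


def _make_library(assets, config: ExperimentConfig, bilateral: bool):
    return msp_library(assets["G"], assets["centers"],
                       include_bilateral=bilateral, mesh=assets["mesh"])


def run_cell(assets, config: ExperimentConfig, placement: str, regime: str,
             snr_db: float, bilateral: bool, schemes=None) -> pd.DataFrame:
    """All simulations of one grid cell; one row per scheme x simulation."""
    schemes = schemes or config.schemes
    g = config.grid
    m = config.metrics
    sizes = default_search_sizes(m.n_search_sizes, m.search_lo_mm,
                                 m.search_hi_mm)
    mesh, L, centers = assets["mesh"], assets["L"], assets["centers"]
    needs_library = any(s in ("ARD", "GS") for s in schemes)
    library = _make_library(assets, config, bilateral) if needs_library else None

    rows = []
    for sim in range(g.n_simulations):
        sim_seed = (config.seed * 100003 + hash(
            (placement, regime, float(snr_db), bilateral)) % 65521
            + sim * 7919) % (2**31)
        spec = SimulationSpec(
            n_dipoles=_PLACEMENT_NDIP[placement], placement=placement,
            correlation_regime=regime, snr_db=snr_db, n_trials=g.n_trials,
            duration_s=g.duration_s, fs_hz=g.fs_hz,
            freq_mean_hz=g.freq_mean_hz, freq_sd_hz=g.freq_sd_hz,
            seed=sim_seed, snr_power_db=g.snr_power_db)
        ds = simulate(spec, mesh, L, centers, locations=assets["locations"])
        T = temporal_projector(
            np.einsum("un,tns->tus", assets["U"], ds.epochs),
            variance_fraction=config.variance_fraction)
        model = reduce_model(ds.epochs, assets["U"], T, L, fs_hz=g.fs_hz)
        for scheme in schemes:
            # a fresh library per run is not needed: hyperparameters are
            # re-estimated from scratch; sensor factors are cached
            res = invert(model, scheme, library=library,
                         per_trial=config.per_trial)
            peaks = find_local_maxima(res.image, mesh, m.peak_rel_threshold)
            sai = compute_sai(peaks, ds.true_vertices, mesh, sizes)
            tai = compute_tai(res, model, ds.true_vertices, mesh, sizes)
            hs = int(np.argmin(np.abs(sizes - m.sai_search_mm)))
            rows.append({
                "placement": placement, "regime": regime, "snr_db": snr_db,
                "bilateral": bilateral, "sim": sim, "sim_seed": sim_seed,
                "scheme": scheme, "F": res.F_final,
                "n_active": len(res.active_components),
                "nu": model.nu, "u": model.u,
                "sai_headline": float(sai.sai[hs]),
                "tai_headline": float(tai.tai_at_size[hs]),
                "tai_auc": tai.tai_auc,
                **{f"sai_{s:.1f}mm": float(v)
                   for s, v in zip(sizes, sai.sai)},
                **{f"tai_{s:.1f}mm": float(v)
                   for s, v in zip(sizes, tai.tai_at_size)},
            })
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the whole grid, resumably; returns the results directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    assets = prepare_assets(config)
    g = config.grid

    bilateral_flags = ([False, True] if (config.library.bilateral
                                         and any(s in ("ARD", "GS")
                                                 for s in config.schemes))
                       else [config.library.bilateral])
    cells = [(p, r, s, b)
             for p in g.placements
             for r in g.correlation_regimes
             for s in g.snr_db
             for b in bilateral_flags]

    seeds_used = {"master": config.seed}
    failures = []
    for placement, regime, snr, bilateral in cells:
        name = f"{placement}_{regime}_snr{snr:+g}_{'bi' if bilateral else 'uni'}"
        cell_path = out / f"cell_{name}.tsv"
        if cell_path.exists():
            logger.info("skipping completed cell %s", name)
            continue
        logger.info("running cell %s", name)
        try:
            df = run_cell(assets, config, placement, regime, snr, bilateral)
        except Exception:
            failures.append({"cell": name,
                             "traceback": traceback.format_exc()})
            logger.exception("cell %s failed; continuing", name)
            continue
        df.to_csv(cell_path, sep="\t", index=False)
        seeds_used[name] = sorted(df["sim_seed"].unique().tolist())

    summary = _merge_cells(out)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "seeds": seeds_used,
        "n_rows": int(len(summary)),
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _merge_cells(out: Path) -> pd.DataFrame:
    parts = sorted(out.glob("cell_*.tsv"))
    if not parts:
        return pd.DataFrame()
    return pd.concat([pd.read_csv(p, sep="\t") for p in parts],
                     ignore_index=True)


def write_report(out_dir: str | Path, plots: bool = True) -> list[Path]:
    """Aggregate tables (and optional accuracy-vs-SNR plots) for a run."""
    out = Path(out_dir)
    summary = pd.read_csv(out / "summary.tsv", sep="\t")
    if summary.empty:
        raise ValueError(f"no completed cells under {out}")
    written = [out / "summary.tsv"]

    agg = (summary.groupby(["placement", "regime", "bilateral", "snr_db",
                            "scheme"])
           .agg(sai_mean=("sai_headline", "mean"),
                sai_sem=("sai_headline", "sem"),
                tai_mean=("tai_headline", "mean"),
                F_mean=("F", "mean"), n=("sim", "count"))
           .reset_index())
    agg_path = out / "accuracy_by_snr.tsv"
    agg.to_csv(agg_path, sep="\t", index=False)
    written.append(agg_path)

    if plots:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            logger.warning("matplotlib unavailable; tables written, plots skipped")
            return written
        for (placement, regime, bilateral), sub in agg.groupby(
                ["placement", "regime", "bilateral"]):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for scheme, ss in sub.groupby("scheme"):
                ss = ss.sort_values("snr_db")
                ax.errorbar(ss["snr_db"], ss["sai_mean"], yerr=ss["sai_sem"],
                            marker="o", capsize=3, label=scheme)
            ax.set_xlabel("SNR (dB)")
            ax.set_ylabel("SAI")
            ax.set_ylim(-0.05, 1.05)
            ax.legend(fontsize=8)
            tag = f"{placement}_{regime}_{'bi' if bilateral else 'uni'}"
            ax.set_title(tag, fontsize=9)
            fig.tight_layout()
            p = out / f"sai_vs_snr_{tag}.svg"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
    return written
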