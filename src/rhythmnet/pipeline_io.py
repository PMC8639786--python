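"""File formats, configuration, and orchestration of the full analysis.

Epoched recordings travel as HDF5 (``/data`` sites x samples x epochs,
``/fs``, optional ``/condition`` per epoch); site layouts, anatomy tables,
and pair matrices as tab-separated text; band definitions, partitions, and
regression tables as JSON. ``run_pipeline`` chains the stages — simulate
(or load), spectral FC, band definition, network statistics,
structure-function regression — writes every declared artifact together
with a manifest (seed, resolved parameters), and is deterministic for a
fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import netstats, spectral, structfun, synthgen
from .containers import EpochedRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_epochs",
    "write_epochs",
    "read_site_layout",
    "write_site_layout",
    "read_anatomy",
    "write_anatomy",
    "write_matrix",
    "read_matrix",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers

def write_epochs(recording: EpochedRecording, path) -> None:
    """Write an epoched recording to HDF5 (/data, /fs, /condition)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("fs", data=float(recording.fs))
        if recording.condition is not None:
            f.create_dataset(
                "condition",
                data=np.asarray(recording.condition, dtype="S"),
            )


def read_epochs(path, condition: Optional[str] = None) -> EpochedRecording:
    """Read an epoched recording from HDF5, optionally filtering by condition."""
    with h5py.File(path, "r") as f:
        for ds in ("data", "fs"):
            if ds not in f:
                raise KeyError(f"schema error: missing dataset /{ds} in {path}")
        data = f["data"][()]
        fs = float(f["fs"][()])
        cond = None
        if "condition" in f:
            cond = f["condition"][()].astype(str)
    rec = EpochedRecording(data=data, fs=fs, condition=cond)
    if condition is not None:
        rec = rec.select_condition(condition)
    return rec


def write_site_layout(layout: synthgen.SiteLayout, path) -> None:
    """Write a site layout to TSV (one row per site)."""
    df = pd.DataFrame(
        {
            "site_id": layout.site_id,
            "area": layout.area,
            "subject": layout.subject,
            "x_mm": layout.positions[:, 0],
            "y_mm": layout.positions[:, 1],
            "hierarchy_level": [layout.hierarchy_level[a] for a in layout.area],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_site_layout(path) -> synthgen.SiteLayout:
    """Read a site layout TSV back into a :class:`SiteLayout`."""
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "area", "x_mm", "y_mm", "hierarchy_level"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"schema error: missing column(s) {sorted(missing)}")
    positions = df[["x_mm", "y_mm"]].to_numpy(float)
    diff = positions[:, None, :] - positions[None, :, :]
    areas = list(dict.fromkeys(df["area"]))
    levels = dict(zip(df["area"], df["hierarchy_level"].astype(float)))
    centroids = np.stack([positions[df["area"] == a].mean(axis=0) for a in areas])
    cdiff = centroids[:, None, :] - centroids[None, :, :]
    return synthgen.SiteLayout(
        site_id=df["site_id"].tolist(),
        area=df["area"].to_numpy(),
        subject=str(df["subject"].iloc[0]) if "subject" in df else "unknown",
        positions=positions,
        hierarchy_level=levels,
        surface_distance=np.sqrt((diff**2).sum(-1)),
        areas=areas,
        area_distance=pd.DataFrame(np.sqrt((cdiff**2).sum(-1)),
                                   index=areas, columns=areas),
    )


def write_anatomy(anatomy: pd.DataFrame, path) -> None:
    anatomy.to_csv(path, sep="\t", index=False)


def read_anatomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"source", "target", "n_labeled"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"schema error: missing column(s) {sorted(missing)}")
    return df


def write_matrix(matrix: np.ndarray, site_ids, path) -> None:
    pd.DataFrame(matrix, index=site_ids, columns=site_ids).to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# configuration and orchestration

@dataclass
class PipelineConfig:
    """Resolved parameters of a full synthetic-data analysis run."""

    seed: int = 0
    # synthetic data
    n_areas: int = 6
    sites_per_area: int = 3
    spacing_mm: float = 2.0
    n_epochs: int = 200
    epoch_len_s: float = 1.0
    fs: float = 200.0
    oscillator_bands_hz: tuple = (4.0, 18.0, 34.0, 75.0)
    pole_radius: float = 0.92
    coupling_strength: float = 0.1
    fc_decay_per_mm: float = 0.04
    anatomy_lambda: float = 0.202
    anatomy_sigma: float = 1.0
    anatomy_neurons: int = 100_000
    anatomy_sln_slope: float = 1.5
    # spectral
    n_tapers: int = 3
    pad_to_s: Optional[float] = None
    gc_tol: float = 1e-9
    gc_max_iter: int = 100
    # bands / significance
    peak_prominence: float = 0.1
    n_randomizations: int = 100
    # networks
    gamma_min: float = 0.1
    gamma_max: float = 10.0
    gamma_points: int = 25
    louvain_reps: int = 10
    consensus_tau: float = 0.25
    strength_radius_mm: float = 2.0
    interareal_min_mm: float = 4.0
    n_perm: int = 1000
    fdr_q: float = 0.2
    alpha: float = 0.05
    # structure-function
    min_neurons: int = 10
    bonferroni_m: int = 12
    n_boot: int = 100
    ci_level: float = 0.999
    sln_ff_cut: float = 0.7
    sln_fb_cut: float = 0.3
    # stage toggles
    run_structfun: bool = True
    # io
    output_dir: Optional[str] = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "oscillator_bands_hz" in raw:
            raw["oscillator_bands_hz"] = tuple(raw["oscillator_bands_hz"])
        return cls(**raw)


def _rhythm_name(pf: float) -> str:
    """Canonical rhythm label for a peak frequency (Hz)."""
    if pf < 8.0:
        return "theta"
    if pf < 25.0:
        return "beta"
    if pf < 45.0:
        return "high_beta"
    return "gamma"


def _band_matrices(coeffs, freqs, fc_type, band_defs, gc_kwargs=None):
    return {
        b.name: bands_mod._band_fc_from_coeffs(coeffs, freqs, fc_type, b, gc_kwargs)
        for b in band_defs
    }


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the full synthetic-data analysis and return (and optionally write) results.

    Stages: generate layout + band-coupled VAR recording + anatomy; estimate
    coherence / power-correlation / GC spectra; define rhythm bands blindly
    from per-site spectral peaks; band-average the FC matrices and compute
    distinctiveness, node strengths (with permutation significance), and
    consensus modularity; relate area-level FC to FLNe (EDR fit, log-log
    regression with fold change, multiple regression with VIF and
    delta-R^2). Deterministic given ``config.seed``; if ``output_dir`` is
    set, all artifacts plus a manifest are written there.
    """
    cfg = config
    results: Dict[str, object] = {"config": dataclasses.asdict(cfg)}
    rng = np.random.default_rng(cfg.seed)

    # --- synthesize
    layout = synthgen.generate_site_layout(
        cfg.n_areas, cfg.sites_per_area, cfg.spacing_mm, seed=cfg.seed
    )
    n_sites = layout.n_sites
    osc = np.asarray(cfg.oscillator_bands_hz, float)
    site_freqs = osc[np.arange(n_sites) % osc.size]
    model = synthgen.band_coupled_var_model(
        layout, site_freqs, fs=cfg.fs, pole_radius=cfg.pole_radius,
        coupling_strength=cfg.coupling_strength,
        decay_per_mm=cfg.fc_decay_per_mm,
    )
    recording = synthgen.simulate_var_lfp(
        layout, model, cfg.n_epochs, cfg.epoch_len_s,
        seed=int(rng.integers(2**31 - 1)), condition="post_cue",
    )
    anatomy = synthgen.generate_anatomy(
        layout,
        synthgen.AnatomyGenConfig(
            lambda_decay=cfg.anatomy_lambda,
            lognormal_sigma=cfg.anatomy_sigma,
            total_neurons_per_injection=cfg.anatomy_neurons,
            sln_slope=cfg.anatomy_sln_slope,
            seed=int(rng.integers(2**31 - 1)),
        ),
    )
    results["layout"] = layout
    results["anatomy"] = anatomy

    # --- spectral FC
    freqs, coeffs = spectral.taper_fourier_coefficients(
        recording, cfg.n_tapers, cfg.pad_to_s
    )
    csd = spectral.multitaper_csd(recording, cfg.n_tapers, cfg.pad_to_s)
    coherence = spectral.coherence_from_csd(csd)
    powcorr = spectral.power_correlation((freqs, coeffs))
    gc = spectral.pairwise_spectral_gc(csd, tol=cfg.gc_tol,
                                       max_iter=cfg.gc_max_iter)
    results["fc_spectra"] = {"coherence": coherence, "powcorr": powcorr, "gc": gc}

    # --- blind band definition: peaks detected per site on the log power
    # spectrum, pooled across sites, and assigned to canonical rhythm ranges;
    # sites lacking a peak simply do not contribute to that rhythm's band
    same_area = layout.area[:, None] == layout.area[None, :]
    near = layout.surface_distance < cfg.interareal_min_mm
    pair_ok = ~(same_area | near)
    np.fill_diagonal(pair_ok, False)
    psd = np.diagonal(csd.csd, axis1=1, axis2=2).real
    pooled: Dict[str, list] = {}
    for s in range(n_sites):
        for pf, fwhm in bands_mod.detect_spectral_peaks(
            np.log10(np.maximum(psd[:, s], 1e-300)), freqs,
            min_prominence=cfg.peak_prominence,
        ):
            pooled.setdefault(_rhythm_name(pf), []).append((pf, fwhm))
    band_defs = []
    for name, fallback_pf in zip(("theta", "beta", "high_beta", "gamma"), osc):
        if name in pooled:
            pfs, fwhms = np.array(pooled[name]).T
            band_defs.append(bands_mod.BandDefinition(
                name=name, subject=layout.subject,
                pf=float(np.mean(pfs)), fwhm=float(max(np.mean(fwhms), 1.0)),
            ))
        else:
            # rhythm without a detectable peak: fall back to the generator band
            band_defs.append(bands_mod.BandDefinition(
                name=name, subject=layout.subject, pf=float(fallback_pf),
                fwhm=3.0,
            ))
    results["bands"] = band_defs

    # --- band matrices, significance, network statistics
    gc_kwargs = {"tol": cfg.gc_tol, "max_iter": cfg.gc_max_iter}
    coh_bands = _band_matrices(coeffs, freqs, "coherence", band_defs)
    pc_bands = _band_matrices(coeffs, freqs, "powcorr", band_defs)
    gc_bands = {
        b.name: gc.values[:, :, b.bins(freqs)].mean(axis=-1) for b in band_defs
    }
    results["band_matrices"] = {
        "coherence": coh_bands, "powcorr": pc_bands, "gc": gc_bands,
    }
    mask = bands_mod.fc_significance_mask(
        recording, "coherence", band_defs[-1],
        n_randomizations=cfg.n_randomizations,
        seed=int(rng.integers(2**31 - 1)), n_tapers=cfg.n_tapers,
        pad_to_s=cfg.pad_to_s,
    )
    results["significance_mask"] = mask

    names = [b.name for b in band_defs]
    dist = layout.surface_distance
    D = {}
    for k1 in range(len(names)):
        for k2 in range(k1 + 1, len(names)):
            D[(names[k1], names[k2])] = netstats.distinctiveness(
                coh_bands[names[k1]], coh_bands[names[k2]], distance=dist
            )
    results["distinctiveness"] = D
    results["strength"] = {
        b: netstats.node_strength(coh_bands[b], dist, cfg.strength_radius_mm)
        for b in names
    }
    results["strength_significance"] = netstats.strength_significance(
        coh_bands[names[-1]], n_perm=max(cfg.n_perm, 100), fdr_q=cfg.fdr_q,
        alpha=cfg.alpha, seed=int(rng.integers(2**31 - 1)),
        site_distances=dist, min_radius_mm=cfg.strength_radius_mm,
    )
    results["modularity"] = netstats.consensus_modularity(
        gc_bands,
        gamma_range=np.logspace(np.log10(cfg.gamma_min), np.log10(cfg.gamma_max),
                                cfg.gamma_points),
        n_reps=cfg.louvain_reps, consensus_tau=cfg.consensus_tau,
        seed=int(rng.integers(2**31 - 1)),
    )

    # --- structure-function
    if cfg.run_structfun:
        filt = structfun.filter_min_neurons(anatomy, cfg.min_neurons)
        edr = structfun.edr_fit(filt["flne"].to_numpy(),
                                filt["dist_wm_mm"].to_numpy())
        results["edr"] = edr
        # area-level directed GC per band vs same-direction FLNe
        area_idx = {a: layout.site_indices(a) for a in layout.areas}
        regs = {}
        for b in names:
            W = gc_bands[b]
            fc_area, flne_vals = [], []
            for _, row in filt.iterrows():
                si, ti = area_idx[row["source"]], area_idx[row["target"]]
                block = W[np.ix_(si, ti)]
                ok = pair_ok[np.ix_(si, ti)]
                if ok.any():
                    fc_area.append(block[ok].mean())
                    flne_vals.append(row["flne"])
            regs[b] = structfun.fc_flne_regression(
                np.asarray(fc_area), np.asarray(flne_vals),
                bonferroni_m=cfg.bonferroni_m,
            )
        results["fc_flne"] = regs
        # multiple regression: log10(FLNe) ~ band-wise log10(GC) + distance
        fc_mat, flne_vals, dists = [], [], []
        for _, row in filt.iterrows():
            si, ti = area_idx[row["source"]], area_idx[row["target"]]
            ok = pair_ok[np.ix_(si, ti)]
            if not ok.any():
                continue
            fc_mat.append([gc_bands[b][np.ix_(si, ti)][ok].mean() for b in names])
            flne_vals.append(row["flne"])
            dists.append(row["dist_surface_mm"])
        fc_mat = np.asarray(fc_mat)
        if len(flne_vals) >= fc_mat.shape[1] + 4:
            mr = structfun.multiple_regression_flne(
                np.asarray(flne_vals), fc_mat, np.asarray(dists),
                band_names=names,
            )
            results["multiple_regression"] = mr
            results["importance"] = structfun.predictor_importance(
                np.log10(np.asarray(flne_vals)),
                np.column_stack([np.log10(fc_mat), np.asarray(dists)[:, None]]),
                names=names + ["distance"],
            )

    if cfg.output_dir is not None:
        _write_artifacts(results, recording, layout, anatomy, cfg)
    return results


def _write_artifacts(results, recording, layout, anatomy, cfg) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_epochs(recording, out / "epochs.h5")
    write_site_layout(layout, out / "sites.tsv")
    write_anatomy(anatomy, out / "anatomy.tsv")
    for fc_type, mats in results["band_matrices"].items():
        for band, W in mats.items():
            write_matrix(W, layout.site_id, out / f"fc_{fc_type}_{band}.tsv")
    bands_json = [
        {"name": b.name, "subject": b.subject, "pf": b.pf, "fwhm": b.fwhm}
        for b in results["bands"]
    ]
    (out / "bands.json").write_text(json.dumps(bands_json, indent=2))
    mod = results["modularity"]
    (out / "partition.json").write_text(json.dumps({
        "partition": mod.partition.tolist(),
        "q": mod.q,
        "q_per_band": mod.q_per_band,
        "consensus_tau": mod.consensus_threshold,
    }, indent=2))
    summary = {}
    if "edr" in results:
        summary["edr_lambda"] = results["edr"].lam
    if "fc_flne" in results:
        summary["fc_flne"] = {
            b: {"slope": r.slope, "r2": r.r2, "p": r.p,
                "fold_change": r.fold_change}
            for b, r in results["fc_flne"].items()
        }
    if "multiple_regression" in results:
        mr = results["multiple_regression"]
        summary["multiple_regression"] = {
            "r2_full": mr.r2_full,
            "delta_r2": mr.delta_r2,
            "vif": mr.vif,
        }
    (out / "structfun.json").write_text(json.dumps(summary, indent=2))
    cfg.to_yaml(out / "config_resolved.yaml")
    manifest = {
        "seed": cfg.seed,
        "n_sites": layout.n_sites,
        "n_epochs": recording.n_epochs,
        "package": "rhythmnet",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
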