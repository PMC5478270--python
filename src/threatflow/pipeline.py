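"""End-to-end orchestration of the three analysis arms.

Each ``run_*_pipeline`` function simulates (or loads) a cohort, runs the full
stage chain, and returns a JSON-serializable result dictionary; rerunning
with the same config and seed reproduces the stats byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster_inference as ci
from . import dics_source as dics
from . import fmri_conn as fc
from . import meg_spectral as ms
from . import physio
from . import stats_core as st
from .synthio import (
    EmgSimConfig,
    FmriSimConfig,
    MegSimConfig,
    build_block_schedule,
    make_emg_session,
    make_fmri_cohort,
    make_meg_cohort,
)
from .synthio.io import config_json

__all__ = [
    "RunConfig",
    "run_fmri_pipeline",
    "run_meg_pipeline",
    "run_physio_pipeline",
    "write_report",
]


@dataclass
class RunConfig:
    arm: str = "all"  # fmri | meg | physio | all
    seed: int = 0
    out_dir: str | None = None
    voxel_p: float = 0.005
    alpha: float = 0.05
    n_perm: int = 1000
    n_iter: int = 1000  # Monte-Carlo cluster-threshold iterations
    lam: float = 0.05
    fmri: FmriSimConfig = field(default_factory=FmriSimConfig)
    meg: MegSimConfig = field(default_factory=MegSimConfig)
    emg: EmgSimConfig = field(default_factory=EmgSimConfig)

    def __post_init__(self):
        if self.arm not in ("fmri", "meg", "physio", "all"):
            raise ValueError(f"unknown arm {self.arm!r}")
        for name in ("voxel_p", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    def reseeded(self) -> "RunConfig":
        """Copy with the top-level seed pushed into every sim config."""
        return dataclasses.replace(
            self,
            fmri=dataclasses.replace(self.fmri, seed=self.seed),
            meg=dataclasses.replace(self.meg, seed=self.seed),
            emg=dataclasses.replace(self.emg, seed=self.seed),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {k: v for k, v in raw.items() if k in
              {"arm", "seed", "out_dir", "voxel_p", "alpha", "n_perm",
               "n_iter", "lam"}}
        for key, cls_ in (("fmri", FmriSimConfig), ("meg", MegSimConfig),
                          ("emg", EmgSimConfig)):
            if key in raw:
                kw[key] = cls_(**raw[key])
        return cls(**kw)


def _provenance(config: RunConfig) -> dict:
    blob = config_json(
        {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    )
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.seed,
    }


def _cluster_rows(result: ci.ClusterResult, positions=None) -> list[dict]:
    rows = []
    for c in result.clusters:
        row = {
            "size": c.size,
            "mass": round(c.mass, 6),
            "sign": c.sign,
            "peak_node": c.peak_node,
            "p_corrected": None if c.p_corrected is None else round(c.p_corrected, 6),
        }
        if positions is not None:
            row["peak_position"] = [round(float(v), 4) for v in positions[c.peak_node]]
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# fMRI arm
# ---------------------------------------------------------------------------

def run_fmri_pipeline(config: RunConfig, cohort=None, truth=None) -> dict:
    """Censor -> nuisance -> GBC -> whole-brain t -> voxelwise clusters ->
    seed follow-up -> shock/motion robustness ANCOVA."""
    config = config.reseeded()
    if cohort is None:
        cohort, truth = make_fmri_cohort(config.fmri)
    rng = np.random.default_rng(config.seed + 1)
    mask = cohort[0].mask
    adjacency = ci.grid_adjacency(mask)
    voxel_mm = config.fmri.voxel_size_mm

    gbc_safe, gbc_threat, residual_subjects = [], [], []
    for ts in cohort:
        resid = fc.nuisance_regress(ts, tr_s=config.fmri.tr_s)
        residual_subjects.append(resid)
        gbc_safe.append(fc.gbc_map(resid, "safe").values)
        gbc_threat.append(fc.gbc_map(resid, "threat").values)
    gbc_safe = np.array(gbc_safe)
    gbc_threat = np.array(gbc_threat)

    wb = st.PairedSample(gbc_safe.mean(axis=1), gbc_threat.mean(axis=1))
    wb_t, wb_df, wb_p = st.paired_t(wb)

    diffs = gbc_threat - gbc_safe
    t_map = diffs.mean(axis=0) / (
        diffs.std(axis=0, ddof=1) / np.sqrt(diffs.shape[0])
    )
    # ACF from one residual subject (cheap desk-scale stand-in for the
    # per-subject average), then the Monte-Carlo cluster-size null
    resid_vols = np.zeros((40, *mask.shape))
    take = residual_subjects[0].data[:, :40]
    resid_vols[:, mask] = take.T
    acf = ci.estimate_acf(resid_vols, mask, voxel_size_mm=voxel_mm)
    thresh = ci.simulate_cluster_threshold(
        mask, acf, voxel_p=config.voxel_p, n_iter=config.n_iter,
        alpha=config.alpha, voxel_size_mm=voxel_mm, rng=rng,
    )
    clusters = ci.extract_clusters(
        t_map, df=wb_df, voxel_p=config.voxel_p, adjacency=adjacency
    )
    significant = [
        c for c in clusters.clusters if c.size > thresh.min_cluster_size
    ]

    seed_rows, robust = [], []
    enorm = {ts.subject_id: fc.motion_enorm(ts.motion) for ts in cohort}
    for c in significant:
        # seed follow-up from this cluster
        seed_safe, seed_threat, adj_diffs, motion_cov = [], [], [], []
        for ts, resid in zip(cohort, residual_subjects):
            m_safe = fc.seed_connectivity(resid, c.nodes, "safe").values
            m_threat = fc.seed_connectivity(resid, c.nodes, "threat").values
            seed_safe.append(m_safe)
            seed_threat.append(m_threat)
            # robustness: censor shocks + matched safe frames, re-extract means
            flags, _ = fc.shock_censor(
                ts.labels, ts.shock_frames, ts.run_index,
                base_censor=ts.censor,
            )
            extra_threat = np.flatnonzero(flags & ~ts.censor & (ts.labels == "threat"))
            safe_pool = np.flatnonzero(~flags & (ts.labels == "safe"))
            if extra_threat.size and safe_pool.size >= extra_threat.size:
                matched = fc.matched_motion_censor(
                    extra_threat, safe_pool, enorm[ts.subject_id]
                )
                flags[matched] = True
            re_ts = fc.SubjectTimeseries(
                data=resid.data, mask=mask, labels=ts.labels, censor=flags,
                motion=ts.motion, run_index=ts.run_index,
                subject_id=ts.subject_id,
            )
            g_safe = fc.gbc_map(re_ts, "safe").values[c.nodes].mean()
            g_threat = fc.gbc_map(re_ts, "threat").values[c.nodes].mean()
            adj_diffs.append(g_threat - g_safe)
            e = enorm[ts.subject_id]
            motion_cov.append(
                e[(ts.labels == "threat") & ~flags].mean()
                - e[(ts.labels == "safe") & ~flags].mean()
            )
        F, df1, df2, p = st.ancova_on_differences(adj_diffs, motion_cov)
        robust.append({"cluster_peak": c.peak_node, "F": round(F, 4),
                       "df": [df1, df2], "p": round(p, 6)})
        sd = np.array(seed_threat) - np.array(seed_safe)
        seed_t = sd.mean(axis=0) / (sd.std(axis=0, ddof=1) / np.sqrt(sd.shape[0]))
        seed_clusters = ci.extract_clusters(
            seed_t, df=wb_df, voxel_p=config.voxel_p, adjacency=adjacency
        )
        seed_rows.append(
            {
                "seed_peak_node": c.peak_node,
                "clusters": _cluster_rows(seed_clusters, adjacency.positions)[:10],
            }
        )

    result = {
        "arm": "fmri",
        "provenance": _provenance(config),
        "whole_brain": {"t": round(wb_t, 6), "df": wb_df, "p": round(wb_p, 6)},
        "acf": {"a": round(acf.a, 4), "b": round(acf.b, 4), "c": round(acf.c, 4)},
        "min_cluster_size": thresh.min_cluster_size,
        "clusters": _cluster_rows(clusters, adjacency.positions)[:10],
        "significant_clusters": [
            {"peak_node": c.peak_node, "size": c.size, "mass": round(c.mass, 6)}
            for c in significant
        ],
        "seed_followup": seed_rows,
        "robustness_ancova": robust,
    }
    if truth is not None and truth.hub_voxels is not None:
        hub = set(truth.hub_voxels.tolist())
        result["ground_truth_check"] = {
            "peak_in_hub": bool(int(np.argmax(t_map)) in hub),
            "hub_hit": any(
                bool(hub & set(c.nodes.tolist())) for c in significant
            ),
        }
    return result


# ---------------------------------------------------------------------------
# MEG arm
# ---------------------------------------------------------------------------

def run_meg_pipeline(config: RunConfig, cohort=None, model=None, truth=None) -> dict:
    """Preprocess -> artifact rejection -> IAF -> band power -> sensor and
    source cluster tests -> trial-count ANCOVA."""
    config = config.reseeded()
    if cohort is None:
        cohort, model, truth = make_meg_cohort(config.meg)
    rng = np.random.default_rng(config.seed + 2)

    profiles, clean_subjects = [], []
    for raw in cohort:
        flags = ms.detect_muscle_artifacts(raw)
        raw.reject = raw.reject | flags
        clean = ms.preprocess_epochs(raw)
        clean_subjects.append(clean)
        spec = ms.mtm_spectrum(clean, fmin=1.0, fmax=20.0, n_tapers=1)
        mean_spec = spec.mean_over(clean.kept())
        profiles.append(ms.detect_iaf(mean_spec, spec.frequencies))
    detected = [p.iaf_hz for p in profiles if p.iaf_hz is not None]
    if not detected:
        raise RuntimeError("no subject produced an in-band alpha peak")
    cohort_iaf = float(np.mean(detected))
    profiles = [p.resolved(cohort_iaf) for p in profiles]

    sensor_diffs, trial_deltas = [], []
    for clean, prof in zip(clean_subjects, profiles):
        power = ms.iaf_band_power(clean, prof)
        safe_idx, threat_idx = clean.kept("safe"), clean.kept("threat")
        sensor_diffs.append(
            power[threat_idx].mean(axis=0) - power[safe_idx].mean(axis=0)
        )
        trial_deltas.append(threat_idx.size - safe_idx.size)
    sensor_diffs = np.array(sensor_diffs)
    adjacency = ci.sensor_adjacency(cohort[0].sensor_positions, radius=0.05)
    sensor_result = ci.permutation_cluster_test(
        sensor_diffs, adjacency, n_perm=config.n_perm,
        node_p=config.voxel_p, alpha=config.alpha, rng=rng,
    )

    source_diffs = []
    for clean, prof in zip(clean_subjects, profiles):
        band = prof.band
        csd_all = dics.compute_csd(clean, band, trials=clean.kept())
        filters = dics.dics_filters(csd_all, model, lam=config.lam)
        p_safe = dics.project_source_power(
            filters, dics.compute_csd(clean, band, trials=clean.kept("safe"))
        )
        p_threat = dics.project_source_power(
            filters, dics.compute_csd(clean, band, trials=clean.kept("threat"))
        )
        source_diffs.append(p_threat - p_safe)
    source_diffs = np.array(source_diffs)
    src_adjacency = ci.sensor_adjacency(
        model.positions, radius=1.5 * model.grid_spacing
    )
    source_result = ci.permutation_cluster_test(
        source_diffs, src_adjacency, n_perm=config.n_perm,
        node_p=config.voxel_p, alpha=config.alpha, rng=rng,
    )

    sig_sensor = sensor_result.significant(config.alpha)
    sensor_cluster_mean = (
        sensor_diffs[:, sig_sensor[0].nodes].mean(axis=1)
        if sig_sensor
        else sensor_diffs.mean(axis=1)
    )
    trial_deltas = np.asarray(trial_deltas, float)
    if np.ptp(trial_deltas) > 0:
        F, df1, df2, p = st.ancova_on_differences(sensor_cluster_mean, trial_deltas)
    else:  # equal trial counts everywhere: covariate is void, use the paired t
        t_eq, df_eq, p = st.paired_t(
            st.PairedSample(np.zeros_like(sensor_cluster_mean), sensor_cluster_mean)
        )
        F, df1, df2 = t_eq**2, 1, df_eq

    result = {
        "arm": "meg",
        "provenance": _provenance(config),
        "cohort_iaf_hz": round(cohort_iaf, 4),
        "subjects": [
            {
                "iaf_hz": round(p_.iaf_hz, 4),
                "fallback": bool(p_.fallback),
                "n_rejected": int(c.reject.sum()),
            }
            for p_, c in zip(profiles, clean_subjects)
        ],
        "sensor_clusters": _cluster_rows(sensor_result),
        "source_clusters": _cluster_rows(source_result, model.positions),
        "trial_count_ancova": {
            "F": round(F, 4), "df": [df1, df2], "p": round(p, 6)
        },
    }
    if truth is not None and truth.active_sources is not None:
        sig_src = source_result.significant(config.alpha)
        near = set()
        for a in truth.active_sources:
            d = np.linalg.norm(model.positions - model.positions[a], axis=1)
            near |= set(np.flatnonzero(d <= 1.5 * model.grid_spacing).tolist())
        result["ground_truth_check"] = {
            "negative_sensor_cluster": any(c.sign < 0 for c in sig_sensor),
            "source_cluster_near_active": any(
                bool(near & set(c.nodes.tolist())) for c in sig_src
            ),
        }
    return result


# ---------------------------------------------------------------------------
# physiology arm
# ---------------------------------------------------------------------------

def run_physio_pipeline(config: RunConfig, n_subjects: int = 12) -> dict:
    """Startle scoring -> T-scores -> APS -> paired tests -> APS x rating r."""
    config = config.reseeded()
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for s in range(n_subjects):
        schedules = build_block_schedule("meg", config.meg, rng)
        gain = max(float(rng.normal(1.0, 0.4)), 0.05)
        trace, ratings, _ = make_emg_session(
            config.emg, schedules, rng=rng, subject_gain=gain
        )
        peaks = physio.score_all_probes(trace)
        summary = physio.condition_summary(
            peaks=peaks,
            conditions=trace.conditions,
            habituation=trace.habituation,
            rating_values=ratings.loc[~ratings.habituation, "rating"].to_numpy(),
            rating_conditions=ratings.loc[~ratings.habituation, "condition"].to_numpy(),
        )
        rows.append(summary)
    startle = st.PairedSample(
        np.array([r.startle_safe_t for r in rows]),
        np.array([r.startle_threat_t for r in rows]),
    )
    rating = st.PairedSample(
        np.array([r.rating_safe_t for r in rows]),
        np.array([r.rating_threat_t for r in rows]),
    )
    t_s, df_s, p_s = st.paired_t(startle)
    t_r, df_r, p_r = st.paired_t(rating)
    r, df_c, p_c = st.pearson_r(startle.differences, rating.differences)
    return {
        "arm": "physio",
        "provenance": _provenance(config),
        "startle_t": {"t": round(t_s, 6), "df": df_s, "p": round(p_s, 6)},
        "rating_t": {"t": round(t_r, 6), "df": df_r, "p": round(p_r, 6)},
        "aps_rating_corr": {"r": round(r, 6), "df": df_c, "p": round(p_c, 6)},
        "mean_aps": round(float(startle.differences.mean()), 6),
    }


def write_report(results: dict, out_dir=None) -> str:
    """Render a deterministic human-readable summary of one or more arms."""
    lines = ["# Safe/threat analysis report", ""]
    for arm in ("fmri", "meg", "physio"):
        res = results.get(arm)
        if res is None:
            continue
        lines.append(f"## {arm} arm")
        prov = res.get("provenance", {})
        lines.append(
            f"seed={prov.get('seed')} config_hash={prov.get('config_hash')}"
        )
        if arm == "fmri":
            wb = res["whole_brain"]
            lines.append(
                f"whole-brain GBC paired t({wb['df']}) = {wb['t']:.3f}, "
                f"p = {wb['p']:.4f}"
            )
            lines.append(f"min cluster size = {res['min_cluster_size']}")
            lines.append("clusters (size, mass, sign, corrected p):")
            for c in res["clusters"]:
                lines.append(
                    f"  {c['size']}\t{c['mass']:.2f}\t{c['sign']}\t{c['p_corrected']}"
                )
        elif arm == "meg":
            lines.append(f"cohort IAF = {res['cohort_iaf_hz']} Hz")
            n_fb = sum(s["fallback"] for s in res["subjects"])
            lines.append(f"fallback IAF subjects: {n_fb}/{len(res['subjects'])}")
            for space in ("sensor_clusters", "source_clusters"):
                lines.append(f"{space}:")
                for c in res[space]:
                    lines.append(
                        f"  size={c['size']} mass={c['mass']:.2f} "
                        f"p={c['p_corrected']}"
                    )
            a = res["trial_count_ancova"]
            lines.append(
                f"trial-count ANCOVA F({a['df'][0]},{a['df'][1]}) = {a['F']}, "
                f"p = {a['p']}"
            )
        else:
            srow = res["startle_t"]
            rrow = res["rating_t"]
            lines.append(
                f"startle paired t({srow['df']}) = {srow['t']:.3f}; "
                f"ratings paired t({rrow['df']}) = {rrow['t']:.3f}"
            )
            corr = res["aps_rating_corr"]
            lines.append(
                f"APS x rating-difference r({corr['df']}) = {corr['r']:.3f}"
            )
        lines.append("")
    text = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(text)
        (out / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True)
        )
    return text
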