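"""End-to-end orchestration: dataset -> migration, adhesion, protrusion, report.

``run_pipeline`` chains the stages of the dose-response analysis:

1. obtain data (simulate a dose-condition bundle, or load one from disk);
2. migration statistics: MSD + PRW fit per cell, per-dose medians and
   coefficients of variation, 2-means slow/fast speed cutoff;
3. adhesion pipeline: segment, track, filter, summarize each movie;
4. protrusion mapping: edge-velocity maps and wave metrics per movie;
5. distribution comparison: per characteristic, averaged pairwise KS under
   EGF binning (no/low/high) and pairwise KS under speed binning
   (slow/fast), KS-minimization distribution fits, group means with t-test
   flags.

The report is a plain JSON-serializable dict, deterministic for a given
config (including seeds).  When ``config.out_dir`` is set, all intermediate
tables and the report are written under a run-stamped subdirectory
``run_seed<seed>``; inputs are never modified in place.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .adhesions import analyze_fa_movie
from .compare import (egf_group_label, fit_distribution, group_by_egf,
                      group_by_speed, ks_statistic, mean_difference_test,
                      mean_pairwise_ks)
from .config import RunConfig
from .migration import (PRWModel, coefficient_of_variation, kmeans_speed_cutoff)
from .protrusion import sector_velocities, wave_metrics
from .simulate import (ConditionMap, ConditionOverrides, DEFAULT_CONDITIONS,
                       EdgeSimParams, FAMovieParams, PRWParams,
                       make_condition_dataset)

__all__ = ["run_pipeline", "save_dataset", "load_dataset", "condition_map_from_config"]

logger = logging.getLogger("famotion")

#: the six adhesion characteristics and the parametric family fitted to each
#: (positive, right-skewed properties -> lognormal; sliding speed -> Weibull)
FA_CHARACTERISTICS = {
    "intensity": "lognormal",
    "area": "lognormal",
    "sliding_speed": "weibull",
    "lifetime": "lognormal",
    "elongation": "lognormal",
    "number_per_cell": "lognormal",
}


def condition_map_from_config(config: RunConfig) -> ConditionMap:
    """Build the synthetic-experiment condition map a config describes."""
    if config.null_conditions:
        base = ConditionOverrides()
        conditions = {dose: base for dose in DEFAULT_CONDITIONS}
    else:
        conditions = dict(DEFAULT_CONDITIONS)
    return ConditionMap(
        conditions=conditions,
        n_cells_per_dose=config.n_cells_per_dose,
        n_fa_movies_per_dose=config.n_fa_movies_per_dose,
        n_edge_movies_per_dose=config.n_edge_movies_per_dose,
        prw=PRWParams(dt=config.track_dt_min, duration=config.track_duration_min,
                      n_cells=config.n_cells_per_dose, seed=config.seed),
        fa=FAMovieParams(frame_shape=tuple(config.fa_frame_shape),
                         pixel_size=config.pixel_size,
                         frame_interval=config.fa_frame_interval,
                         n_frames=config.fa_n_frames, seed=config.seed),
        edge=EdgeSimParams(noise_sd=0.25, n_frames=config.edge_n_frames,
                           n_sectors=config.n_sectors, seed=config.seed),
        couple_waves_to_speed=not config.null_conditions,
    )


def save_dataset(bundle: dict, root) -> Path:
    """Write a condition bundle to disk (tracks CSV, TIFF movies + sidecars)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    all_tracks = []
    index = {}
    for dose, data in sorted(bundle.items()):
        tag = f"dose_{dose:g}".replace(".", "p")
        ddir = root / tag
        ddir.mkdir(exist_ok=True)
        all_tracks.extend(data["trajectories"])
        entry = {"egf_nM": dose, "fa_movies": [], "edge_movies": []}
        for i, fm in enumerate(data["fa_movies"]):
            path = ddir / f"fa_movie_{i}.tif"
            fio.write_tiff_stack(path, fm["movie"].frames,
                                 fm["movie"].pixel_size,
                                 fm["movie"].frame_interval,
                                 seed=fm["params"].seed, params=fm["params"])
            entry["fa_movies"].append(
                {"path": str(path.relative_to(root)),
                 "cell_speed_um_hr": fm["cell_speed_um_hr"]})
        for i, em in enumerate(data["edge_movies"]):
            path = ddir / f"edge_movie_{i}.tif"
            fio.write_tiff_stack(path, em["masks"],
                                 em["params"].pixel_size,
                                 em["params"].frame_interval,
                                 seed=em["params"].seed, params=em["params"])
            entry["edge_movies"].append(
                {"path": str(path.relative_to(root)),
                 "cell_speed_um_hr": em["cell_speed_um_hr"]})
        index[f"{dose:g}"] = entry
    fio.write_tracks_csv(all_tracks, root / "tracks.csv")
    (root / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return root


def load_dataset(root) -> dict:
    """Load a dataset directory written by :func:`save_dataset`."""
    root = Path(root)
    index = json.loads((root / "index.json").read_text())
    trajectories = fio.read_tracks_csv(root / "tracks.csv")
    bundle = {}
    for key, entry in index.items():
        dose = float(key)
        fa_movies = []
        for rec in entry["fa_movies"]:
            movie = fio.read_tiff_stack(root / rec["path"])
            fa_movies.append(dict(movie=movie, truth=None,
                                  cell_speed_um_hr=rec["cell_speed_um_hr"],
                                  params=None))
        edge_movies = []
        for rec in entry["edge_movies"]:
            masks, meta = fio.read_tiff_stack(root / rec["path"])
            edge_movies.append(dict(masks=masks, truth=None,
                                    meta=meta,
                                    cell_speed_um_hr=rec["cell_speed_um_hr"],
                                    params=None))
        bundle[dose] = dict(
            trajectories=[t for t in trajectories if t.egf_dose == dose],
            fa_movies=fa_movies,
            edge_movies=edge_movies,
            cell_speeds=None,
        )
    return bundle


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _migration_stage(bundle, config):
    rows = []
    for dose, data in sorted(bundle.items()):
        for traj in data["trajectories"]:
            res = PRWModel.from_trajectory(traj).fit(max_fit_lag=config.max_fit_lag_min)
            rows.append(dict(cell_id=traj.cell_id, egf_nM=dose,
                             S_um_per_hr=res.speed, P_hr=res.persistence,
                             residual_ss=res.residual_ss,
                             converged=res.converged,
                             identifiability_flag=res.identifiability_flag))
    table = pd.DataFrame(rows)
    per_dose = {}
    for dose, g in table.groupby("egf_nM"):
        per_dose[f"{dose:g}"] = dict(
            n=int(len(g)),
            median_S_um_per_hr=float(g["S_um_per_hr"].median()),
            median_P_hr=float(g["P_hr"].median()),
            cv_S=coefficient_of_variation(g["S_um_per_hr"]),
            cv_P=coefficient_of_variation(g["P_hr"]),
        )
    if config.speed_cutoff is not None:
        cutoff, cutoff_source = float(config.speed_cutoff), "config"
        part_ss = None
    else:
        part = kmeans_speed_cutoff(table["S_um_per_hr"].to_numpy())
        cutoff, cutoff_source = part.cutoff, "kmeans"
        part_ss = part.within_cluster_ss
    logger.info("migration: %d cells, speed cutoff %.2f um/hr (%s)",
                len(table), cutoff, cutoff_source)
    return table, dict(per_dose=per_dose, speed_cutoff_um_per_hr=cutoff,
                       cutoff_source=cutoff_source,
                       within_cluster_ss=part_ss)


def _adhesion_stage(bundle, config):
    fa_rows, count_rows = [], []
    qc_flags = []
    for dose, data in sorted(bundle.items()):
        for mi, fm in enumerate(data["fa_movies"]):
            movie = fm["movie"]
            result = analyze_fa_movie(
                movie, min_area=config.min_fa_area_um2,
                max_area=config.max_fa_area_um2,
                max_disp_um=config.max_link_disp_um,
                gap_frames=config.gap_frames,
            )
            summary = result["summary"]
            summary = summary.assign(egf_nM=dose, movie=mi,
                                     cell_speed_um_hr=fm["cell_speed_um_hr"])
            fa_rows.append(summary)
            for t, c in enumerate(result["counts"]):
                count_rows.append(dict(egf_nM=dose, movie=mi, frame=t,
                                       count=int(c),
                                       cell_speed_um_hr=fm["cell_speed_um_hr"]))
            if result["qc"] is not None:
                qc_flags.append(dict(egf_nM=dose, movie=mi, **result["qc"]))
            logger.info("adhesions: dose %g movie %d -> %d tracks kept",
                        dose, mi, len(result["tracks"]))
    fa_table = pd.concat(fa_rows, ignore_index=True) if fa_rows else pd.DataFrame()
    counts = pd.DataFrame(count_rows)
    return fa_table, counts, qc_flags


def _protrusion_stage(bundle, config):
    rows = []
    maps = []
    for dose, data in sorted(bundle.items()):
        for mi, em in enumerate(data["edge_movies"]):
            if em.get("params") is not None:
                px = em["params"].pixel_size
                dt = em["params"].frame_interval
            else:
                px = em["meta"]["pixel_size"]
                dt = em["meta"]["frame_interval"]
            emap = sector_velocities(em["masks"], px, dt,
                                     n_sectors=config.n_sectors)
            wm = wave_metrics(emap)
            rows.append(dict(egf_nM=dose, movie=mi,
                             cell_speed_um_hr=em["cell_speed_um_hr"],
                             velocity_std=wm.velocity_std,
                             wave_flag=wm.wave_flag,
                             wave_speed=wm.wave_speed,
                             correlation_peak=wm.correlation_peak))
            maps.append(dict(egf_nM=dose, cell_speed_um_hr=em["cell_speed_um_hr"],
                             edge_map=emap))
    return pd.DataFrame(rows), maps


def _characteristic_samples(fa_table, counts):
    """Dose/speed-tagged sample arrays per adhesion characteristic.

    Each entry is ``(doses, speeds, values, test_tuple)``.  ``test_tuple``
    carries the statistically independent units for mean testing; it differs
    from the pooled values only for FA number per cell, whose per-frame
    measurements are strongly autocorrelated within one cell -- there the
    independent unit is the cell (movie) and the test statistic its mean
    count.
    """
    out = {}
    uncensored = fa_table[~fa_table["censored"]]
    multi = fa_table[np.isfinite(fa_table["slide_um_per_hr"])]
    pos = fa_table[fa_table["mean_intensity"] > 0]
    out["intensity"] = (pos["egf_nM"], pos["cell_speed_um_hr"],
                        pos["mean_intensity"], None)
    out["area"] = (fa_table["egf_nM"], fa_table["cell_speed_um_hr"],
                   fa_table["area_um2"], None)
    out["sliding_speed"] = (multi["egf_nM"], multi["cell_speed_um_hr"],
                            multi["slide_um_per_hr"], None)
    out["lifetime"] = (uncensored["egf_nM"], uncensored["cell_speed_um_hr"],
                       uncensored["lifetime_s"], None)
    out["elongation"] = (fa_table["egf_nM"], fa_table["cell_speed_um_hr"],
                         fa_table["elongation"], None)
    nz = counts[counts["count"] > 0]
    per_cell = nz.groupby(["egf_nM", "movie"]).agg(
        mean_count=("count", "mean"),
        cell_speed_um_hr=("cell_speed_um_hr", "first")).reset_index()
    out["number_per_cell"] = (
        nz["egf_nM"], nz["cell_speed_um_hr"], nz["count"].astype(float),
        (per_cell["egf_nM"], per_cell["cell_speed_um_hr"],
         per_cell["mean_count"]),
    )
    def arr(t):
        return tuple(np.asarray(x, float) for x in t)
    return {k: arr((d, s, v)) + (None if t is None else arr(t),)
            for k, (d, s, v, t) in out.items()}


def _compare_one(groups: dict, family: str, alpha, equal_var, extreme: tuple,
                 test_groups: dict | None = None):
    """KS summary + fits + extreme-pair mean test for one grouped sample set.

    ``test_groups``, when given, holds the independent units the mean test
    runs on (the KS summaries and fits always use the pooled ``groups``).
    """
    labels = list(groups)
    result = dict(group_n={l: int(groups[l].size) for l in labels},
                  group_means={l: float(np.mean(groups[l])) for l in labels})
    if len(groups) == 3:
        result["mean_pairwise_ks"] = mean_pairwise_ks(groups)
    elif len(groups) == 2:
        result["pairwise_ks"] = ks_statistic(groups[labels[0]], groups[labels[1]])
    fits = {}
    for l in labels:
        x = groups[l]
        if family in ("lognormal", "weibull"):
            x = x[x > 0]
        try:
            f = fit_distribution(x, family)
            fits[l] = dict(family=family, params=list(f.params),
                           ks_distance=f.ks_distance)
        except ValueError as exc:
            fits[l] = dict(family=family, error=str(exc))
    result["fits"] = fits
    a, b = extreme
    tg = groups if test_groups is None else test_groups
    if a in tg and b in tg and tg[a].size >= 2 and tg[b].size >= 2:
        try:
            t, p, sig = mean_difference_test(tg[a], tg[b], alpha=alpha,
                                             equal_var=equal_var)
            result["mean_test"] = dict(pair=[a, b], t=t, p=p, significant=sig)
        except ValueError as exc:
            result["mean_test"] = dict(pair=[a, b], error=str(exc))
    return result


def _compare_stage(fa_table, counts, prot_table, maps, cutoff, config):
    samples = _characteristic_samples(fa_table, counts)
    report = {}
    for name, (doses, speeds, values, test) in samples.items():
        family = FA_CHARACTERISTICS[name]
        entry = {}
        if config.scheme in ("egf", "both"):
            gs = group_by_egf(doses, values)
            tg = None if test is None else group_by_egf(test[0], test[2]).groups
            entry["egf"] = _compare_one(gs.groups, family, config.alpha,
                                        config.equal_var_ttest, ("no", "high"),
                                        test_groups=tg)
        if config.scheme in ("speed", "both"):
            gs = group_by_speed(speeds, values, cutoff)
            tg = (None if test is None
                  else group_by_speed(test[1], test[2], cutoff).groups)
            entry["speed"] = _compare_one(gs.groups, family, config.alpha,
                                          config.equal_var_ttest,
                                          ("slow", "fast"), test_groups=tg)
        report[name] = entry

    # protrusion velocity distributions under both schemes; the mean test
    # runs on per-cell mean velocities (map entries within one movie are
    # strongly correlated, the cell is the independent unit)
    prot = {}
    vel_by_speed, vel_by_egf = {}, {}
    cellmean_by_speed, cellmean_by_egf = {}, {}
    for rec in maps:
        v = rec["edge_map"].velocities.ravel()
        sl = "fast" if rec["cell_speed_um_hr"] > cutoff else "slow"
        gl = egf_group_label(rec["egf_nM"])
        vel_by_speed.setdefault(sl, []).append(v)
        vel_by_egf.setdefault(gl, []).append(v)
        cellmean_by_speed.setdefault(sl, []).append(float(v.mean()))
        cellmean_by_egf.setdefault(gl, []).append(float(v.mean()))
    if config.scheme in ("speed", "both") and len(vel_by_speed) == 2:
        g = {k: np.concatenate(v) for k, v in vel_by_speed.items()}
        tg = {k: np.asarray(v) for k, v in cellmean_by_speed.items()}
        prot["speed"] = _compare_one(g, "gaussian", config.alpha,
                                     config.equal_var_ttest, ("slow", "fast"),
                                     test_groups=tg)
    if config.scheme in ("egf", "both") and len(vel_by_egf) == 3:
        g = {k: np.concatenate(v) for k, v in vel_by_egf.items()}
        tg = {k: np.asarray(v) for k, v in cellmean_by_egf.items()}
        prot["egf"] = _compare_one(g, "gaussian", config.alpha,
                                   config.equal_var_ttest, ("no", "high"),
                                   test_groups=tg)
    # wave indicators by speed group
    wave = {}
    for sl, g in prot_table.assign(
            group=np.where(prot_table["cell_speed_um_hr"] > cutoff,
                           "fast", "slow")).groupby("group"):
        wave[sl] = dict(
            n=int(len(g)),
            wave_fraction=float(g["wave_flag"].mean()),
            mean_velocity_std=float(g["velocity_std"].mean()),
        )
    if {"slow", "fast"} <= set(wave) and \
            prot_table["velocity_std"].std(ddof=1) > 0:
        slow_std = prot_table.loc[prot_table["cell_speed_um_hr"] <= cutoff,
                                  "velocity_std"]
        fast_std = prot_table.loc[prot_table["cell_speed_um_hr"] > cutoff,
                                  "velocity_std"]
        if len(slow_std) >= 2 and len(fast_std) >= 2:
            t, p, sig = mean_difference_test(slow_std, fast_std,
                                             alpha=config.alpha,
                                             equal_var=config.equal_var_ttest)
            wave["velocity_std_test"] = dict(t=t, p=p, significant=sig)
    return dict(fa_characteristics=report, protrusion=prot, waves=wave)


def _write_histograms(fa_table, counts, cutoff, run_dir, bins=40):
    """Per-characteristic histogram CSV, one row per (scheme, group, bin)."""
    samples = _characteristic_samples(fa_table, counts)
    rows = []
    for name, (doses, speeds, values, _) in samples.items():
        finite = np.isfinite(values)
        if not finite.any():
            continue
        edges = np.histogram_bin_edges(values[finite], bins=bins)
        for scheme, keys in (("egf", doses), ("speed", speeds)):
            if scheme == "egf":
                grouped = group_by_egf(keys[finite], values[finite]).groups
            else:
                grouped = group_by_speed(keys[finite], values[finite], cutoff).groups
            for label, x in grouped.items():
                hist, _ = np.histogram(x, bins=edges)
                for lo, hi, c in zip(edges[:-1], edges[1:], hist):
                    rows.append(dict(characteristic=name, scheme=scheme,
                                     group=label, bin_low=lo, bin_high=hi,
                                     count=int(c)))
    pd.DataFrame(rows).to_csv(run_dir / "histograms.csv", index=False,
                              float_format="%.8g")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``; return the report dict."""
    logger.info("pipeline start: seed=%d scheme=%s", config.seed, config.scheme)
    if config.simulate:
        cmap = condition_map_from_config(config)
        bundle = make_condition_dataset(cmap, seed=config.seed)
    else:
        bundle = load_dataset(config.data_dir)

    mig_table, migration = _migration_stage(bundle, config)
    cutoff = migration["speed_cutoff_um_per_hr"]
    fa_table, counts, qc_flags = _adhesion_stage(bundle, config)
    prot_table, maps = _protrusion_stage(bundle, config)
    comparison = _compare_stage(fa_table, counts, prot_table, maps, cutoff, config)

    report = dict(
        config=config.to_dict(),
        migration=migration,
        adhesion_qc=qc_flags,
        comparison=comparison,
        n_fa_tracks=int(len(fa_table)),
        n_edge_movies=int(len(prot_table)),
    )
    report = _round_floats(report)

    if config.out_dir:
        run_dir = Path(config.out_dir) / f"run_seed{config.seed}"
        run_dir.mkdir(parents=True, exist_ok=True)
        mig_table.to_csv(run_dir / "migration_fits.csv", index=False,
                         float_format="%.8g")
        fa_table.to_csv(run_dir / "fa_properties.csv", index=False,
                        float_format="%.8g")
        counts.to_csv(run_dir / "fa_number_per_cell.csv", index=False)
        prot_table.to_csv(run_dir / "protrusion_metrics.csv", index=False,
                          float_format="%.8g")
        for i, rec in enumerate(maps):
            fio.write_edge_map_csv(rec["edge_map"],
                                   run_dir / f"edge_map_{i}.csv")
        _write_histograms(fa_table, counts, cutoff, run_dir)
        (run_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        logger.info("outputs written to %s", run_dir)
    return report
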