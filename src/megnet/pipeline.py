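"""End-to-end orchestration: simulate -> preprocess -> spectral -> beamform
-> connect -> graph -> stats, with a provenance manifest.

Each stage is a plain function over the library types; ``run_pipeline``
wires them in dependency order, writes every artifact under the
configured output directory and records checksums so identical
config + seed reruns are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .beamformer import compute_filters, project_sources, source_power
from .config import RunConfig
from .connectivity import aggregate_to_regions, build_high_res_network, octant_atlas
from .forward import compute_leadfield
from .geometry import HeadModel, build_source_grid, make_sensor_cap
from .graph import compute_graph_measures, nodal_strength
from .preprocessing import bandpass
from .simulate import ActiveSource, CoupledPair, SimulationConfig, make_cohort
from .spectral import get_band, multitaper_csd
from .stats import (PermutationScheme, fdr_regional, mann_whitney, nbs,
                    node_cluster_permutation, power_cluster_test)

logger = logging.getLogger("megnet")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    config_hash: str
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    elapsed_s: dict = field(default_factory=dict)

    def write(self, path) -> None:
        # atomic: write then rename
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                  default=mio._coerce))
        tmp.replace(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(cfg: RunConfig) -> SimulationConfig:
    sim = cfg.simulation
    pairs = tuple(
        CoupledPair(node_a=int(p["node_a"]), node_b=int(p["node_b"]),
                    band=str(p["band"]), phase_lag=float(p["phase_lag"]),
                    coupling_strength=float(p["coupling_strength"]),
                    amplitude=float(p.get("amplitude", 1.0)),
                    signal_id=p.get("signal_id"))
        for p in sim.coupled_pairs
    )
    actives = tuple(
        ActiveSource(node=int(a["node"]), orientation=tuple(a["orientation"]),
                     band=str(a["band"]), amplitude=float(a.get("amplitude", 1.0)))
        for a in sim.active_nodes
    )
    return SimulationConfig(
        n_subjects_per_group=(sim.n_patients, sim.n_controls),
        n_epochs=sim.n_epochs,
        epoch_length_s=sim.epoch_length_s,
        fs=sim.fs,
        active_nodes=actives,
        coupled_pairs=pairs,
        planted_group_effect=sim.planted_group_effect,
        sensor_noise_sd=sim.sensor_noise_sd,
        dipole_moment=sim.dipole_moment,
        seed=cfg.seed,
    )


def analyze_cohort_band(
    subjects,
    grid,
    lf,
    band_name: str,
    lam: float = 0.05,
    atlas=None,
) -> dict:
    """Beamform and network-build one band for an in-memory cohort.

    ``subjects`` is the ``make_cohort`` output list.  Returns per-group
    stacks of nodal strengths (high resolution), region-level adjacency
    matrices, depth-normalized source power maps, plus the retained node
    ids and region labels — the inputs the group statistics consume.
    """
    band = get_band(band_name)
    atlas = atlas if atlas is not None else octant_atlas(grid)
    out: dict = {"strengths": {}, "networks_low": {}, "power": {},
                 "node_ids": None, "region_labels": None}
    for sid, group, rec in subjects:
        spec, csd = multitaper_csd(rec.data, rec.fs, band)
        filters = compute_filters(lf, csd, lam=lam)
        src = project_sources(filters, spec)
        if out["node_ids"] is None:
            out["node_ids"] = src.node_ids
        elif not np.array_equal(out["node_ids"], src.node_ids):
            raise RuntimeError(f"subject {sid}: retained node set differs")
        wn = np.sum(filters.weights[filters.kept_nodes] ** 2, axis=1)
        net_hi = build_high_res_network(src, grid=grid, subject_id=sid)
        net_lo = aggregate_to_regions(net_hi, atlas, node_ids=src.node_ids)
        out["region_labels"] = net_lo.node_labels
        out["strengths"].setdefault(group, []).append(
            nodal_strength(net_hi.adjacency)[0])
        out["networks_low"].setdefault(group, []).append(net_lo.adjacency)
        out["power"].setdefault(group, []).append(
            source_power(src, weights_norm=wn).power)
    for key in ("strengths", "networks_low", "power"):
        out[key] = {g: np.array(v) for g, v in out[key].items()}
    return out


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages and return the provenance manifest.

    Outputs under ``cfg.output_dir``: per-subject recordings and networks
    (HDF5), graph-measure tables (TSV), statistics (JSON), the ground
    truth manifest and the run manifest (JSON).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config=cfg_dict, config_hash=cfg_hash)

    t0 = time.time()
    head = HeadModel(radius=cfg.geometry.head_radius)
    sensors = make_sensor_cap(head, n_sensors=cfg.geometry.n_sensors,
                              radius_factor=cfg.geometry.sensor_radius_factor)
    grid = build_source_grid(head, cfg.geometry.grid_spacing)
    lf = compute_leadfield(grid, sensors, head)
    if lf.degenerate_nodes:
        manifest.warnings.append(
            {"stage": "forward", "excluded_nodes": list(lf.degenerate_nodes)})
    manifest.elapsed_s["forward"] = round(time.time() - t0, 3)
    logger.info("forward model: %d sensors, %d nodes", sensors.count, grid.n_nodes)

    t0 = time.time()
    subjects, truth = make_cohort(_sim_config(cfg), grid, lf, sensors)
    mio.save_json(out / "ground_truth.json", truth)
    manifest.elapsed_s["simulate"] = round(time.time() - t0, 3)

    t0 = time.time()
    pre = cfg.preprocessing
    cleaned = [
        (sid, group, bandpass(rec, pre.bandpass_low, pre.bandpass_high,
                              pre.butter_order))
        for sid, group, rec in subjects
    ]
    manifest.elapsed_s["preprocess"] = round(time.time() - t0, 3)

    group_a, group_b = "patient", "control"
    stats_out: dict = {}
    measures_rows = []
    for band_name in cfg.spectral.bands:
        t0 = time.time()
        band = get_band(band_name)
        nets_high: dict[str, list[np.ndarray]] = {group_a: [], group_b: []}
        nets_low: dict[str, list[np.ndarray]] = {group_a: [], group_b: []}
        powers: dict[str, list[np.ndarray]] = {group_a: [], group_b: []}
        common_kept: np.ndarray | None = None
        atlas = octant_atlas(grid)
        for sid, group, rec in cleaned:
            spec, csd = multitaper_csd(rec.data, rec.fs, band,
                                       mode=cfg.spectral.mode)
            filters = compute_filters(lf, csd, lam=cfg.beamformer.lam)
            if common_kept is None:
                common_kept = filters.kept_nodes
            elif not np.array_equal(common_kept, filters.kept_nodes):
                raise RuntimeError(
                    f"stage beamformer, subject {sid}, band {band_name}: "
                    f"retained node set differs across subjects")
            src = project_sources(filters, spec)
            wn = np.sum(filters.weights[filters.kept_nodes] ** 2, axis=1)
            powers[group].append(source_power(src, weights_norm=wn).power)
            net_hi = build_high_res_network(src, grid=grid, subject_id=sid)
            net_hi.band = band
            net_lo = aggregate_to_regions(net_hi, atlas, node_ids=src.node_ids)
            nets_high[group].append(net_hi.adjacency)
            nets_low[group].append(net_lo.adjacency)
            mio.save_network(out / f"net_{sid}_{band_name}_high.h5", net_hi)
            mio.save_network(out / f"net_{sid}_{band_name}_low.h5", net_lo)
            for res_name, net in (("high", net_hi), ("low", net_lo)):
                gm = compute_graph_measures(net, n_surrogates=cfg.graph.n_surrogates,
                                            seed=cfg.seed)
                measures_rows.append({
                    "subject": sid, "group": group, "band": band_name,
                    "resolution": res_name,
                    "global_strength": gm.global_strength,
                    "global_clustering": gm.global_clustering,
                    "char_path_length": gm.char_path_length,
                    "normalized_clustering": gm.normalized_clustering,
                    "normalized_path_length": gm.normalized_path_length,
                })

        node_pos = grid.positions[common_kept]
        scheme_nodes = PermutationScheme(
            n_permutations=cfg.stats.n_permutations,
            threshold=cfg.stats.node_t_threshold,
            alpha=cfg.stats.node_alpha, seed=cfg.seed)
        scheme_nbs = PermutationScheme(
            n_permutations=cfg.stats.n_permutations,
            threshold=cfg.stats.nbs_t_threshold,
            alpha=cfg.stats.nbs_alpha, seed=cfg.seed)
        scheme_power = PermutationScheme(
            n_permutations=cfg.stats.n_permutations,
            threshold=cfg.stats.power_t_threshold,
            alpha=cfg.stats.power_alpha, seed=cfg.seed)

        strengths = {g: np.array([nodal_strength(a)[0] for a in nets_high[g]])
                     for g in (group_a, group_b)}
        regional = {g: np.array([nodal_strength(a)[0] for a in nets_low[g]])
                    for g in (group_a, group_b)}
        global_strength = {g: strengths[g].mean(axis=1) for g in (group_a, group_b)}

        band_stats = {
            "global_strength_mwu": mann_whitney(
                global_strength[group_a], global_strength[group_b]).__dict__,
            "node_clusters": [
                {"members": c.members, "statistic": c.statistic,
                 "p_value": c.p_value, "sign": c.sign,
                 "significant": c.p_value < cfg.stats.node_alpha}
                for c in node_cluster_permutation(
                    strengths[group_a], strengths[group_b], node_pos,
                    cfg.geometry.grid_spacing, scheme_nodes)
            ],
            "regional_fdr": [
                {"region": r.extra["region"], "p": r.p_value,
                 "p_adjusted": r.extra["p_adjusted"],
                 "significant": r.extra["significant"]}
                for r in fdr_regional(regional[group_a], regional[group_b],
                                      q=cfg.stats.fdr_q)
            ],
            "nbs_components": [
                {"edges": c.members, "statistic": c.statistic,
                 "p_value": c.p_value, "sign": c.sign,
                 "significant": c.p_value < cfg.stats.nbs_alpha}
                for c in nbs(np.array(nets_low[group_a]),
                             np.array(nets_low[group_b]), scheme_nbs)
            ],
            "power_clusters": [
                {"members": c.members, "statistic": c.statistic,
                 "p_value": c.p_value, "sign": c.sign,
                 "significant": c.p_value < cfg.stats.power_alpha}
                for c in power_cluster_test(
                    np.array(powers[group_a]), np.array(powers[group_b]),
                    node_pos, cfg.geometry.grid_spacing, scheme_power)
            ],
        }
        stats_out[band_name] = band_stats
        manifest.elapsed_s[f"band_{band_name}"] = round(time.time() - t0, 3)
        logger.info("band %s done in %.1f s", band_name,
                    manifest.elapsed_s[f"band_{band_name}"])

    import pandas as pd

    pd.DataFrame(measures_rows).to_csv(out / "graph_measures.tsv", sep="\t",
                                       index=False)
    mio.save_json(out / "stats.json", stats_out)

    for p in sorted(out.glob("*")):
        if p.name != "run_manifest.json" and p.is_file():
            manifest.outputs[p.name] = _sha256(p)
    manifest.write(out / "run_manifest.json")
    return manifest
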