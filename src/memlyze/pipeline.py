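"""End-to-end analysis driver: configuration, stages, reports, comparisons.

``run_pipeline`` executes every analysis stage on one system (and optionally
a pure-membrane reference): windowed density profiles, RMSD/RMSF, secondary
structure evolution/content/propensity with the inter-peptide strand ratio,
GROMOS clustering, stratified area per lipid, acyl order parameters,
hydrogen-bond census, lateral RDF with the 80%-area cutoff and residence
times. Outputs are TSV files whose header comments record the config hash
and stage parameters, plus a JSON manifest; everything is deterministic
under a fixed seed and inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_summary, extract_structures, gromos_cluster, pairwise_rmsd_matrix
from .conformation import density_profile, profile_overlap, rmsd_series, rmsf
from .core import SelectionError, Trajectory, select_atoms
from .fileio import read_trajectory
from .interactions import cutoff_from_rdf, hbond_census, lateral_rdf, residence_time
from .membrane import apl_table, order_parameters
from .secondary import (
    ss_content,
    ss_evolution,
    ss_propensity,
    strand_propensity_ratio,
)
from .strands import DEFAULT_STRAND_MAP
from .synthetic import SyntheticSpec, simulate

__all__ = ["AnalysisConfig", "run_pipeline", "compare_systems"]

DEFAULT_SELECTIONS = {
    "peptide": "kind peptide and heavy",
    "backbone": "backbone",
    "calpha": "calpha",
    "head_atom": "name P",
}


@dataclass
class AnalysisConfig:
    """Pipeline parameters; defaults follow the study's printed thresholds
    (cluster cutoff 0.25 nm, regions at 0.5/1.0 nm, RDF area fraction 0.8).
    """

    trajectory: str | None = None
    reference_trajectory: str | None = None
    synthetic: dict | None = None            # SyntheticSpec kwargs
    reference_synthetic: dict | None = None
    selections: dict = field(default_factory=lambda: dict(DEFAULT_SELECTIONS))
    cluster_cutoff: float = 0.25             # nm
    cluster_stride: int = 1
    region_bounds: tuple[float, float] = (0.5, 1.0)   # nm
    region_distance_mode: str = "3d"         # "3d" | "lateral"
    rdf_fraction: float = 0.8
    rdf_bin_width: float = 0.05              # nm
    grid: int = 200
    density_bins: int = 100
    window_fraction: float = 0.25            # first/last analysis windows
    apl_stride: int = 1
    gap_tolerance: int = 0
    seed: int = 0
    out_dir: str = "memlyze_out"

    def __post_init__(self) -> None:
        sel = dict(DEFAULT_SELECTIONS)
        sel.update(self.selections or {})
        self.selections = sel
        self.region_bounds = tuple(self.region_bounds)
        if self.region_distance_mode not in ("3d", "lateral"):
            raise ValueError("region_distance_mode must be '3d' or 'lateral'")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["region_bounds"] = list(self.region_bounds)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.as_dict()
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_system(config: AnalysisConfig, synthetic_key: str, path_key: str,
                 seed_offset: int = 0):
    synth = getattr(config, synthetic_key)
    path = getattr(config, path_key)
    if synth is not None:
        kwargs = dict(synth)
        kwargs.setdefault("seed", config.seed + seed_offset)
        if "melt_schedule" in kwargs:
            kwargs["melt_schedule"] = tuple(
                tuple(entry) for entry in kwargs["melt_schedule"]
            )
        spec = SyntheticSpec(**kwargs)
        traj, truth = simulate(spec)
        return traj, truth
    if path is not None:
        return read_trajectory(path), None
    return None, None


def _write_tsv(path: Path, df: pd.DataFrame, header: dict) -> None:
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _select(traj: Trajectory, query: str, allow_empty: bool = False) -> np.ndarray:
    try:
        return select_atoms(traj.topology, query, allow_empty=allow_empty)
    except SelectionError:
        if allow_empty:
            return np.array([], dtype=int)
        raise


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage; write TSV outputs and a manifest; return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    manifest: dict = {
        "version": __version__,
        "config_hash": h,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    report: dict = {"config_hash": h}

    def record(stage: str, ok: bool, detail: str = "") -> None:
        manifest["stages"][stage] = {"ok": ok, "detail": detail}

    def emit(name: str, df: pd.DataFrame, **params) -> None:
        path = out / name
        _write_tsv(path, df, {"config": h, **params})
        manifest["outputs"].append(name)

    traj, truth = _load_system(config, "synthetic", "trajectory")
    if traj is None:
        raise ValueError("config names neither a trajectory nor a synthetic system")
    ref_traj, _ = _load_system(config, "reference_synthetic",
                               "reference_trajectory", seed_offset=1)
    topo = traj.topology

    peptide = _select(traj, config.selections["peptide"], allow_empty=True)
    has_peptide = len(peptide) > 0
    heads = _select(traj, config.selections["head_atom"], allow_empty=True)
    n_win = max(1, int(round(config.window_fraction * traj.n_frames)))

    # --- density profiles, first/last windows -----------------------------
    groups = {"heads": heads if len(heads) else None,
              "peptide": peptide if has_peptide else None}
    water = _select(traj, "kind water", allow_empty=True)
    if len(water):
        groups["water"] = water
    rows = []
    profiles = {}
    for gname, sel in groups.items():
        if sel is None:
            continue
        for wname, window in (("first", (0, n_win)),
                              ("last", (traj.n_frames - n_win, traj.n_frames))):
            p = density_profile(traj, sel, n_bins=config.density_bins,
                                frame_range=window, group=gname)
            profiles[(gname, wname)] = p
            rows.append(pd.DataFrame({
                "group": gname, "window": wname,
                "z": p.bin_centers, "density": p.density,
            }))
    density_df = pd.concat(rows, ignore_index=True)
    emit("density.tsv", density_df, bins=config.density_bins,
         window_frames=n_win)
    overlaps = {}
    if ("peptide", "last") in profiles and ("heads", "last") in profiles:
        overlaps["peptide_vs_heads_last"] = profile_overlap(
            profiles[("peptide", "last")], profiles[("heads", "last")]
        )
    report["density"] = density_df
    report["profile_overlap"] = overlaps
    record("density", True)

    # --- RMSD / RMSF -------------------------------------------------------
    if has_peptide:
        backbone = _select(traj, config.selections["backbone"])
        series = rmsd_series(traj, 0, backbone)
        rmsd_df = pd.DataFrame({"time_ps": series.times, "rmsd_nm": series.values})
        emit("rmsd.tsv", rmsd_df, selection=config.selections["backbone"])
        fl = rmsf(traj, backbone)
        rmsf_df = pd.DataFrame({
            "atom_index": backbone, "rmsf_nm": fl.values,
            "residue": topo.resids[backbone], "chain": topo.chain_ids[backbone],
        })
        emit("rmsf.tsv", rmsf_df, selection=config.selections["backbone"])
        report["rmsd"] = rmsd_df
        report["rmsf"] = rmsf_df
        record("rmsd_rmsf", True)
    else:
        record("rmsd_rmsf", True, "no peptide; skipped")

    # --- secondary structure ------------------------------------------------
    ss_ok = has_peptide and np.any(
        (topo.kinds == "peptide") & (topo.names == "O")
    )
    if ss_ok:
        matrix = ss_evolution(traj)
        evo = pd.DataFrame(matrix.labels,
                           columns=[f"f{i}" for i in range(matrix.n_frames)])
        evo.insert(0, "chain", [c for c, _ in matrix.residues])
        evo.insert(1, "residue", [r for _, r in matrix.residues])
        emit("ss_evolution.tsv", evo)
        content = ss_content(matrix)
        content_df = pd.DataFrame([content])
        emit("ss_content.tsv", content_df)
        prop = ss_propensity(matrix)
        prop_df = pd.DataFrame({
            "chain": [c for c, _ in prop.residues],
            "residue": [r for _, r in prop.residues],
            "P_E": prop.p_e, "P_T": prop.p_t, "P_C": prop.p_c,
        })
        emit("ss_propensity.tsv", prop_df)
        ratios = {}
        chains = topo.peptide_chains
        if len(chains) == 2:
            regions = dict(DEFAULT_STRAND_MAP.strands)
            regions["polar"] = DEFAULT_STRAND_MAP.polar_region
            for name, rng in regions.items():
                try:
                    ratios[name] = strand_propensity_ratio(prop, rng, *chains[:2])
                except ValueError:
                    ratios[name] = float("nan")
        report["ss_content"] = content
        report["ss_propensity"] = prop_df
        report["strand_ratio"] = ratios
        record("secondary_structure", True)
    else:
        report["ss_content"] = {}
        record("secondary_structure", True, "no peptide backbone; skipped")

    # --- clustering ----------------------------------------------------------
    calpha = _select(traj, config.selections["calpha"], allow_empty=True)
    if len(calpha) >= 3:
        structures = extract_structures(traj, config.cluster_stride, calpha)
        matrix = pairwise_rmsd_matrix(structures)
        result = gromos_cluster(matrix, config.cluster_cutoff)
        summary = cluster_summary(result, len(structures))
        summary["center_structure"] = result.centers
        emit("clusters.tsv", summary, cutoff=config.cluster_cutoff,
             stride=config.cluster_stride, n_structures=len(structures))
        report["clusters"] = summary
        record("clustering", True)
    else:
        record("clustering", True, "no calpha atoms; skipped")

    # --- area per lipid -------------------------------------------------------
    if len(heads) >= 2:
        table = apl_table(
            traj, peptide if has_peptide else None, grid=config.grid,
            bounds=config.region_bounds,
            lateral=config.region_distance_mode == "lateral",
            stride=config.apl_stride,
        )
        agg = (table.groupby(["leaflet", "region"])["area"]
               .agg(["mean", "std", "count"]).reset_index())
        emit("apl_regions.tsv", agg, grid=config.grid,
             bounds=config.region_bounds, mode=config.region_distance_mode)
        report["apl"] = agg
        if ref_traj is not None:
            ref_table = apl_table(ref_traj, None, grid=config.grid,
                                  stride=config.apl_stride)
            ref_agg = (ref_table.groupby("leaflet")["area"]
                       .agg(["mean", "std"]).reset_index()
                       .rename(columns={"mean": "pure_mean", "std": "pure_std"}))
            cmp_df = agg.merge(ref_agg, on="leaflet")
            cmp_df["delta"] = cmp_df["mean"] - cmp_df["pure_mean"]
            emit("apl_vs_pure.tsv", cmp_df)
            report["apl_vs_pure"] = cmp_df
        record("apl", True)

        scd_rows = []
        for chain_name in traj.topology.acyl_chain_definitions:
            prof = order_parameters(traj, chain_name)
            scd_rows.append(pd.DataFrame({
                "chain": chain_name,
                "carbon": prof.carbon_index,
                "minus_s_cd": prof.minus_s_cd,
            }))
        scd_df = pd.concat(scd_rows, ignore_index=True)
        emit("order_parameters.tsv", scd_df)
        report["scd"] = scd_df
        record("order_parameters", True)
    else:
        record("apl", True, "no lipids; skipped")
        record("order_parameters", True, "no lipids; skipped")

    # --- hydrogen bonds --------------------------------------------------------
    if ss_ok:
        census = hbond_census(traj)
        census_df = pd.DataFrame({
            "category": list(census.mean),
            "mean": list(census.mean.values()),
            "sd": list(census.sd.values()),
        })
        census_df["mean_sd"] = [
            f"{m:.2f}±{s:.2f}" for m, s in zip(census_df["mean"], census_df["sd"])
        ]
        emit("hbond_census.tsv", census_df)
        report["hbonds"] = census_df
        record("hbonds", True)
    else:
        record("hbonds", True, "no peptide backbone; skipped")

    # --- RDF / residence time ---------------------------------------------------
    if has_peptide and len(heads) >= 2:
        rdf = lateral_rdf(traj, heads, peptide, bin_width=config.rdf_bin_width)
        rdf_df = pd.DataFrame({"r": rdf.bin_centers, "g": rdf.g,
                               "N": rdf.cumulative})
        emit("rdf.tsv", rdf_df, bin_width=config.rdf_bin_width)
        cutoff = cutoff_from_rdf(rdf, config.rdf_fraction)
        stats = residence_time(traj, cutoff, peptide,
                               gap_tolerance=config.gap_tolerance)
        res_df = pd.DataFrame([{
            "cutoff_nm": cutoff,
            "tau_ps": stats.tau,
            "n_events": stats.n_events,
            "gap_tolerance": stats.gap_tolerance,
        }])
        emit("residence.tsv", res_df, fraction=config.rdf_fraction)
        report["rdf"] = rdf_df
        report["residence"] = res_df
        record("rdf_residence", True)
    else:
        record("rdf_residence", True, "needs peptide and lipids; skipped")

    if truth is not None:
        report["ground_truth"] = truth
    manifest["ok"] = all(s["ok"] for s in manifest["stages"].values())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    return report


def compare_systems(reports: list[dict], labels: list[str] | None = None
                    ) -> pd.DataFrame:
    """Side-by-side key quantities for several systems, in input order.

    Rows: per-leaflet mean APL, secondary-structure contents, residence time,
    first-cluster percentage; differences are taken against the first system.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    if labels is None:
        labels = [f"system{i + 1}" for i in range(len(reports))]
    if len(labels) != len(reports):
        raise ValueError("one label per report required")

    def extract(rep: dict) -> dict:
        row: dict[str, float] = {}
        apl = rep.get("apl")
        if apl is not None:
            for leaflet in ("top", "bottom"):
                sub = apl[apl.leaflet == leaflet]
                if len(sub):
                    row[f"apl_{leaflet}"] = float(
                        np.average(sub["mean"], weights=sub["count"])
                    )
        for lab, frac in (rep.get("ss_content") or {}).items():
            row[f"ss_{lab}"] = float(frac)
        res = rep.get("residence")
        if res is not None and len(res):
            row["residence_tau_ps"] = float(res["tau_ps"].iloc[0])
        clusters = rep.get("clusters")
        if clusters is not None and len(clusters):
            row["cluster1_pct"] = float(clusters["percentage"].iloc[0])
        return row

    frame = pd.DataFrame({lab: extract(rep) for lab, rep in zip(labels, reports)})
    base = frame[labels[0]]
    for lab in labels[1:]:
        frame[f"delta_{lab}"] = frame[lab] - base
    frame.index.name = "quantity"
    return frame.reset_index()
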