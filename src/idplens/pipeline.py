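"""End-to-end ensemble-analysis pipeline.

One configuration drives the whole chain: sequence annotation, synthetic
ensemble generation (or file ingestion), equilibration trimming and
concatenation, Rg decomposition, per-group SAXS with P(r) (and chi-square
against an experimental curve when provided), SASA, contact and H-bond
maps, secondary structure, Ramachandran fractions, J-couplings, ensemble
CD, tICA landscapes and GROMOS clustering. Every run directory carries a
manifest (config, seed, stage log, library versions) sufficient to re-run
identically.

All physical quantities in config keys carry explicit units (trim_ns,
cutoff_nm, rg_target_A) because the field mixes Angstrom (Rg, SAXS) and nm
(RMSD, SASA, cluster cutoffs).
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
from . import cd_spectra as cdm
from . import constants as C
from . import landscape as lsm
from . import rg_decompose as rgm
from . import saxs as sxm
from . import seqprofile as sqm
from . import structure_obs as som
from . import synthetic as synm
from . import trajio as tio


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized verbatim into the manifest."""

    sequence: str = C.AICD_SEQUENCE
    seed: int = 7
    outdir: str = "idplens_run"
    # ensemble source: synthetic generation or input files
    ensemble_files: list = field(default_factory=list)   # PDB paths, one/replica
    n_replicas: int = 5
    frames_per_replica: int = 2000
    rg_target_A: float | None = None
    rg_spring_kbt_A2: float = 0.0
    time_per_frame_ps: float = 10.0
    trim_ns: float = 0.0
    # decomposition
    bin_width_A: float = 1.0
    groups_A: tuple = (10.0, 15.0, 20.0)
    # SAXS
    saxs_enabled: bool = True
    q_min: float = 0.0078
    q_max: float = 0.495
    n_q: int = 100
    saxs_stride: int = 10
    expt_saxs_path: str | None = None
    pr_dmax_A: float = 45.0
    # observables
    observable_stride: int = 10
    cd_enabled: bool = True
    # tICA / clustering
    tica_lag_frames: int = 100
    tica_scheme: str = "dihedral-sincos"
    cluster_cutoff_nm: float = 0.9
    cluster_max_frames: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _write_matrix(m: np.ndarray, path: Path):
    np.savetxt(path, m, delimiter="\t")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Halts at the first failing stage (naming it), leaving earlier outputs
    in place. Deterministic for a fixed config: identical manifests and
    bit-identical numeric outputs on re-run.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    state: dict = {}

    def stage(name):
        def deco(fn):
            stages.append((name, fn))
            return fn
        return deco

    @stage("sequence_profile")
    def _seq(st):
        if not cfg.sequence:
            raise ValueError("no sequence configured")
        p = sqm.load_peptide(cfg.sequence)
        st["peptide"] = p
        df = sqm.write_profile_tsv(p, out / "sequence_profile.tsv")
        _, net = sqm.charge_profile(p)
        motif = sqm.find_motif(p, "YENPTY")
        (out / "sequence_summary.json").write_text(json.dumps({
            "length": len(p), "net_charge_e": net,
            "molecular_weight_Da": p.molecular_weight,
            "mean_residue_weight_Da": sqm.mean_residue_weight(p),
            "yenpty_location": motif}, indent=1))
        return {"n_residues": len(p)}

    @stage("generate")
    def _gen(st):
        p = st["peptide"]
        if cfg.ensemble_files:
            reps = [tio.read_ensemble(f) for f in cfg.ensemble_files]
        else:
            gcfg = synm.GeneratorConfig(
                seed=cfg.seed, n_replicas=cfg.n_replicas,
                frames_per_replica=cfg.frames_per_replica,
                rg_target=cfg.rg_target_A, rg_spring=cfg.rg_spring_kbt_A2)
            ens = synm.sample_ensemble(p, gcfg)
            reps = [ens.subset(np.flatnonzero(ens.replica == r))
                    for r in range(cfg.n_replicas)]
        reps = [synm.emulate_protocol(r, cfg.time_per_frame_ps) for r in reps]
        st["replicas"] = reps
        return {"n_replicas": len(reps),
                "frames": [int(r.n_frames) for r in reps]}

    @stage("trim_concat")
    def _trim(st):
        ens = tio.trim_and_concatenate(st["replicas"], cfg.trim_ns)
        st["ensemble"] = ens
        return {"frames_out": int(ens.n_frames)}

    @stage("decompose")
    def _dec(st):
        ens = st["ensemble"]
        rg = rgm.ensemble_rg(ens)
        part = rgm.assign_groups(rg, cfg.bin_width_A)
        st["rg"], st["part"] = rg, part
        pd.DataFrame({"frame": np.arange(len(rg)), "rg_A": rg,
                      "group": part.assignment}).to_csv(
            out / "rg_decomposition.tsv", sep="\t", index=False)
        for lab in cfg.groups_A:
            if lab in part.indices:
                tio.write_index(part.indices[lab],
                                out / f"group_rg{lab:g}.ndx")
        rmsd = rgm.rmsd_series(ens, reference=0)
        np.savetxt(out / "rmsd_nm.tsv", rmsd)
        st["groups"] = {lab: ens.subset(part.indices[lab].frames)
                        for lab in cfg.groups_A if lab in part.indices}
        return {"n_groups_total": len(part.labels),
                "selected_groups": {f"{lab:g}": int(g.n_frames)
                                    for lab, g in st["groups"].items()}}

    @stage("saxs")
    def _saxs(st):
        if not cfg.saxs_enabled:
            return {"skipped": True}
        ens = st["ensemble"]
        q = np.geomspace(cfg.q_min, cfg.q_max, cfg.n_q)
        fft = sxm.FormFactorTable.for_topology(ens.topology)
        profiles = {"all": sxm.ensemble_average(ens, fft, q,
                                                stride=cfg.saxs_stride)}
        for lab, g in st["groups"].items():
            profiles[f"rg{lab:g}"] = sxm.ensemble_average(
                g, fft, q, stride=max(1, cfg.saxs_stride // 2))
        st["profiles"], st["fft"], st["q"] = profiles, fft, q
        summary = {}
        for name, sp in profiles.items():
            sxm.write_dat(sp, out / f"saxs_{name}.dat")
            try:
                rgv, diag = sxm.guinier_rg(sp)
                summary[name] = {"guinier_rg_A": rgv, **diag}
            except sxm.SaxsError as e:
                summary[name] = {"guinier_error": str(e)}
        if cfg.expt_saxs_path:
            expt = sxm.read_dat(cfg.expt_saxs_path)
            chi2, scale = sxm.chi_square(expt, profiles["all"], scale="fit")
            summary["chi2_vs_experiment"] = {"chi2": chi2, "scale": scale}
        (out / "saxs_summary.json").write_text(json.dumps(summary, indent=1))
        return {"curves": list(profiles)}

    @stage("pr")
    def _pr(st):
        if not cfg.saxs_enabled:
            return {"skipped": True}
        rows = {}
        for name, sp in st["profiles"].items():
            pr = sxm.pr_indirect(sp, dmax=cfg.pr_dmax_A)
            np.savetxt(out / f"pr_{name}.tsv",
                       np.column_stack([pr.r, pr.P]), delimiter="\t",
                       header="r(A)\tP(r)")
            rows[name] = {"mode_A": pr.mode, "fit_chi2": pr.chi2}
        (out / "pr_summary.json").write_text(json.dumps(rows, indent=1))
        return {"curves": list(rows)}

    @stage("sasa")
    def _sasa(st):
        ens = st["ensemble"]
        sub = ens.subset(np.arange(0, ens.n_frames, cfg.observable_stride))
        sr = som.sasa(sub)
        part_sub = rgm.assign_groups(st["rg"][::cfg.observable_stride],
                                     cfg.bin_width_A)
        summ = som.sasa_group_summary(sr, part_sub)
        summ["totals"].to_csv(out / "sasa_groups.tsv", sep="\t", index=False)
        summ["per_residue"].to_csv(out / "sasa_per_residue.tsv", sep="\t")
        np.savetxt(out / "sasa_residue_variance.tsv",
                   summ["per_residue_variance"])
        st["sasa"], st["sasa_stride"] = sr, cfg.observable_stride
        return {"frames_used": int(sub.n_frames),
                "grand_mean_nm2": summ["grand_mean"]}

    @stage("contacts_hbonds")
    def _maps(st):
        outmeta = {}
        for lab, g in st["groups"].items():
            sub = g.subset(np.arange(0, g.n_frames,
                                     max(1, cfg.observable_stride // 2)))
            _write_matrix(som.min_ca_distance_map(sub),
                          out / f"contact_min_ca_rg{lab:g}.tsv")
            _write_matrix(som.hbond_map(sub),
                          out / f"hbond_occupancy_rg{lab:g}.tsv")
            outmeta[f"{lab:g}"] = int(sub.n_frames)
        return {"frames_used": outmeta}

    @stage("secondary_structure")
    def _ss(st):
        ens = st["ensemble"]
        sub = ens.subset(np.arange(0, ens.n_frames, cfg.observable_stride))
        part_sub = rgm.assign_groups(st["rg"][::cfg.observable_stride],
                                     cfg.bin_width_A)
        res = som.assign_secondary_structure(sub, part_sub)
        pd.DataFrame(res["per_residue"], columns=som.SS_CLASSES,
                     index=np.arange(1, sub.topology.n_residues + 1)
                     ).to_csv(out / "ss_per_residue.tsv", sep="\t")
        res["group_fractions"].to_csv(out / "ss_group_fractions.tsv",
                                      sep="\t")
        st["ss"] = res
        return {"frames_used": int(sub.n_frames)}

    @stage("rama_jcouple")
    def _rj(st):
        ens = st["ensemble"]
        rama = som.ramachandran(ens)
        (out / "rama_fractions.json").write_text(
            json.dumps(rama["fractions"], indent=1))
        np.savetxt(out / "rama_hist.tsv", rama["hist"], delimiter="\t")
        jc = som.j_couplings(ens, part=st["part"])
        jc.to_csv(out / "j_couplings.tsv", sep="\t", index=False)
        return {"n_dihedral_points": rama["n_points"]}

    @stage("cd")
    def _cd(st):
        if not cfg.cd_enabled:
            return {"skipped": True}
        frac5 = np.stack([(st["ss"]["labels"] == k).mean(axis=1)
                          for k in range(5)], axis=1)
        spec = cdm.ensemble_cd(cdm.five_to_four_class(frac5))
        cdm.write_spectrum(spec, out / "cd_simulated.tsv")
        dec = cdm.decompose_cd(spec)
        (out / "cd_decomposition.json").write_text(json.dumps(
            {"fractions": dec["fractions"], "residual": dec["residual"]},
            indent=1))
        return {"n_wavelengths": len(spec.wavelength)}

    @stage("tica_fes")
    def _tica(st):
        ens = st["ensemble"]
        fs = lsm.featurize(ens, cfg.tica_scheme)
        lag = min(cfg.tica_lag_frames,
                  max(1, min(np.bincount(fs.replica.astype(int))) // 4))
        model = lsm.fit_tica(fs, tau=lag)
        proj = model.projections[:, :2]
        pd.DataFrame({"frame": np.arange(len(proj)), "tic1": proj[:, 0],
                      "tic2": proj[:, 1]}).to_csv(
            out / "tica_projections.tsv", sep="\t", index=False)
        fes = lsm.free_energy_surface(proj[:, 0], proj[:, 1], bins=40)
        _write_matrix(fes["F"], out / "fes_kbt.tsv")
        if "sasa" in st:
            stv = st["sasa_stride"]
            sl = lsm.observable_landscape(
                proj[::stv, 0][: len(st["sasa"].total)],
                proj[::stv, 1][: len(st["sasa"].total)],
                st["sasa"].total, bins=40)
            _write_matrix(sl["mean"], out / "sasa_landscape.tsv")
        st["tica"] = model
        return {"lag_frames": int(lag),
                "lambda": [float(v) for v in model.eigenvalues[:3]]}

    @stage("cluster")
    def _clust(st):
        cr = lsm.gromos_cluster(st["ensemble"],
                                cutoff_nm=cfg.cluster_cutoff_nm,
                                max_frames=cfg.cluster_max_frames)
        pd.DataFrame({"cluster": np.arange(len(cr.populations)),
                      "center_frame": cr.centers,
                      "population": cr.populations}).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        return {"n_clusters": len(cr.populations), "stride": cr.stride,
                "top_populations": [round(p, 4)
                                    for p in cr.populations[:4]]}

    manifest = {
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str)
            .encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {"idplens": __version__,
                     "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": [],
    }
    for name, fn in stages:
        try:
            info = fn(state)
        except Exception as e:
            manifest["stages"].append({"stage": name, "status": "failed",
                                       "error": str(e)})
            (out / "manifest.json").write_text(json.dumps(
                manifest, indent=1, default=str))
            raise PipelineError(f"stage '{name}' failed: {e}") from e
        manifest["stages"].append({"stage": name, "status": "ok",
                                   "info": info})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out


def report(run_dir) -> dict:
    """Summary tables of a completed run; a pure function of the directory.

    Returns one table per figure-analog (profiles, SAXS curves, SASA,
    contact maps, H-bond maps, SS fractions, J-couplings, landscapes,
    cluster populations); absent analyses appear under ``missing``.
    """
    run = Path(run_dir)
    tables: dict = {"missing": []}

    def add(key, fn):
        try:
            tables[key] = fn()
        except FileNotFoundError:
            tables["missing"].append(key)

    add("profiles", lambda: pd.read_csv(run / "sequence_profile.tsv",
                                        sep="\t"))
    add("saxs_curves", lambda: {
        f.stem: pd.read_csv(f, sep=r"\s+", comment="#", header=None,
                            names=["q", "I"])
        for f in sorted(run.glob("saxs_*.dat"))} or _raise_fnf())
    add("sasa", lambda: pd.read_csv(run / "sasa_groups.tsv", sep="\t"))
    add("contact_maps", lambda: {
        f.stem: np.loadtxt(f) for f in sorted(run.glob("contact_*.tsv"))}
        or _raise_fnf())
    add("hbond_maps", lambda: {
        f.stem: np.loadtxt(f) for f in sorted(run.glob("hbond_*.tsv"))}
        or _raise_fnf())
    add("ss_fractions", lambda: pd.read_csv(run / "ss_group_fractions.tsv",
                                            sep="\t", index_col=0))
    add("jcouplings", lambda: pd.read_csv(run / "j_couplings.tsv", sep="\t"))
    add("landscapes", lambda: {"fes_kbt": np.loadtxt(run / "fes_kbt.tsv")})
    add("clusters", lambda: pd.read_csv(run / "clusters.tsv", sep="\t"))
    return tables


def _raise_fnf():
    raise FileNotFoundError
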