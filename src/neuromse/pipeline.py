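"""Configured, resumable orchestration of the full analysis.

Stages: simulate -> decompose -> hsa -> entropy -> stats -> classify.
Each stage writes its outputs plus a ``provenance.json`` sidecar holding
the stage parameters, the SHA-256 digests of its inputs and the package
version; a rerun with identical configuration and inputs is skipped
unless forced.  The global seed propagates deterministically to every
stochastic stage, so two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import neuromse
from neuromse.classifier import ARCHITECTURES, CVConfig, SAEParams, double_cv
from neuromse.decomposition import EEMDParams, eemd
from neuromse.entropy import SampEnParams, band_scale_factors, mse_profile
from neuromse.group_stats import (cognition_correlation, correlation_map,
                                  posthoc_ttests, rm_ancova)
from neuromse.hilbert import decompose_band
from neuromse.io import (load_cohort, read_manifest, read_matrix, read_tidy,
                         sha256_of, write_cohort, write_matrix, write_tidy)
from neuromse.synthetic import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "STAGES", "run_stage", "run_all", "demo_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "decompose", "hsa", "entropy", "stats", "classify")


@dataclass
class PipelineConfig:
    output_dir: str = "neuromse_out"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    decompose: dict = field(default_factory=dict)   # EEMDParams fields
    bands: list = field(default_factory=lambda: ["alpha"])
    entropy: dict = field(default_factory=dict)     # SampEnParams fields
    stats: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


def demo_config(output_dir: str = "neuromse_demo", seed: int = 0
                ) -> PipelineConfig:
    """A minutes-scale demonstration configuration (6 subjects, 6 regions)."""
    return PipelineConfig(
        output_dir=output_dir, seed=seed,
        synthetic={"n_per_group": 3, "n_regions": 6, "n_temporal_regions": 2,
                   "n_segments": 2},
        decompose={"n_ensembles": 10},
        bands=["alpha"],
        stats={"factors": ["group"], "covariates": [],
               "region_groups": {"temporal": [0, 1], "frontal": [2, 3],
                                 "posterior": [4, 5]}},
        classify={"n_repeats": 2, "search_budget": 4,
                  "sae": {"n_autoencoders": 4, "n_hidden": 6, "epochs": 60}})


# ---------------------------------------------------------------------------
# provenance


def _provenance_path(stage_dir: Path) -> Path:
    return stage_dir / "provenance.json"


def _write_provenance(stage_dir: Path, stage: str, params: dict,
                      inputs: dict[str, str]) -> None:
    _provenance_path(stage_dir).write_text(json.dumps({
        "stage": stage, "params": params, "inputs": inputs,
        "version": neuromse.__version__}, indent=1, sort_keys=True))


def _up_to_date(stage_dir: Path, stage: str, params: dict,
                inputs: dict[str, str]) -> bool:
    path = _provenance_path(stage_dir)
    if not path.exists():
        return False
    try:
        prov = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    return (prov.get("stage") == stage
            and prov.get("params") == json.loads(json.dumps(params))
            and prov.get("inputs") == inputs
            and prov.get("version") == neuromse.__version__)


def _input_digests(paths: list[Path], root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): sha256_of(p) for p in paths}


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path}; run the '{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, force: bool) -> Path:
    stage_dir = config.out / "data"
    params = {"synthetic": dict(config.synthetic), "seed": config.seed}
    if not force and _up_to_date(stage_dir, "simulate", params, {}):
        logger.info("simulate: up to date, skipped")
        return stage_dir / "manifest.json"
    sim = SimulationConfig(**{**config.synthetic, "seed": config.seed})
    recordings, manifests = generate_cohort(sim)
    manifest_path = write_cohort(recordings, manifests, stage_dir)
    _write_provenance(stage_dir, "simulate", params, {})
    return manifest_path


def _stage_decompose(config: PipelineConfig, force: bool) -> Path:
    manifest_path = _require(config.out / "data" / "manifest.json", "simulate")
    stage_dir = config.out / "imfs"
    params = {"decompose": dict(config.decompose), "seed": config.seed}
    inputs = _input_digests([manifest_path], config.out)
    if not force and _up_to_date(stage_dir, "decompose", params, inputs):
        logger.info("decompose: up to date, skipped")
        return stage_dir / "index.json"
    stage_dir.mkdir(parents=True, exist_ok=True)
    recordings, _ = load_cohort(manifest_path)
    index = []
    counter = 0
    for rec in recordings:
        for seg in range(rec.n_segments):
            for region in range(rec.n_regions):
                eparams = EEMDParams(**{**config.decompose,
                                        "seed": config.seed * 100003 + counter})
                counter += 1
                imfset = eemd(rec.data[seg, region], eparams)
                name = f"{rec.subject_id}_{seg:03d}_r{region:02d}.tsv"
                write_matrix(stage_dir / name,
                             np.vstack(imfset.imfs + [imfset.residual]))
                index.append({"subject": rec.subject_id, "segment": seg,
                              "region": region, "file": name,
                              "n_imfs": len(imfset.imfs)})
    (stage_dir / "index.json").write_text(json.dumps(
        {"fs": recordings[0].fs, "entries": index}, indent=1))
    _write_provenance(stage_dir, "decompose", params, inputs)
    return stage_dir / "index.json"


def _stage_hsa(config: PipelineConfig, force: bool) -> Path:
    index_path = _require(config.out / "imfs" / "index.json", "decompose")
    stage_dir = config.out / "hsa"
    params = {"bands": list(config.bands)}
    inputs = _input_digests([index_path], config.out)
    if not force and _up_to_date(stage_dir, "hsa", params, inputs):
        logger.info("hsa: up to date, skipped")
        return stage_dir / "index.json"
    stage_dir.mkdir(parents=True, exist_ok=True)
    index = json.loads(index_path.read_text())
    out_entries = []
    band_to_imf = {"gamma": 2, "beta": 3, "alpha": 4, "theta": 5}
    for entry in index["entries"]:
        imfs = read_matrix(config.out / "imfs" / entry["file"])
        for band in config.bands:
            row = band_to_imf[band] - 1
            if row >= entry["n_imfs"]:
                logger.warning("hsa: %s lacks IMF for band %s", entry["file"],
                               band)
                continue
            bc = decompose_band(imfs[row], band)
            name = entry["file"].replace(".tsv", f"_{band}.tsv")
            write_matrix(stage_dir / name,
                         np.vstack([bc.spectral, bc.amplitude, bc.cos_phase]))
            out_entries.append({**entry, "band": band, "file": name})
    (stage_dir / "index.json").write_text(json.dumps(
        {"fs": index["fs"], "entries": out_entries}, indent=1))
    _write_provenance(stage_dir, "hsa", params, inputs)
    return stage_dir / "index.json"


def _stage_entropy(config: PipelineConfig, force: bool) -> Path:
    index_path = _require(config.out / "hsa" / "index.json", "hsa")
    stage_dir = config.out / "entropy"
    params = {"entropy": dict(config.entropy), "bands": list(config.bands)}
    inputs = _input_digests([index_path], config.out)
    if not force and _up_to_date(stage_dir, "entropy", params, inputs):
        logger.info("entropy: up to date, skipped")
        return stage_dir / "mse.tsv"
    stage_dir.mkdir(parents=True, exist_ok=True)
    index = json.loads(index_path.read_text())
    sp = SampEnParams(**config.entropy)

    from collections import defaultdict
    from neuromse.hilbert import BandComponents
    groups: dict[tuple, list] = defaultdict(list)
    for entry in index["entries"]:
        groups[(entry["subject"], entry["region"], entry["band"])].append(entry)
    frames = []
    for (subject, region, band), entries in sorted(groups.items()):
        segs = []
        for entry in sorted(entries, key=lambda e: e["segment"]):
            m = read_matrix(config.out / "hsa" / entry["file"])
            segs.append(BandComponents(band=band, spectral=m[0],
                                       amplitude=m[1], cos_phase=m[2]))
        prof = mse_profile(segs, sp, band_scale_factors(band),
                           subject_id=subject, region_id=region)
        frames.append(prof.to_frame())
    tidy = pd.concat(frames, ignore_index=True)
    write_tidy(stage_dir / "mse.tsv", tidy)
    _write_provenance(stage_dir, "entropy", params, inputs)
    return stage_dir / "mse.tsv"


def _profile_matrix(tidy: pd.DataFrame, subjects: list[str], regions: list[int],
                    band: str, component: str) -> np.ndarray:
    """(subjects x 20) profile averaged over ``regions`` for one component."""
    sel = tidy[(tidy["band"] == band) & (tidy["component"] == component)
               & (tidy["region"].isin(regions))]
    pivot = sel.pivot_table(index="subject", columns="scale_factor",
                            values="sampen", aggfunc="mean")
    pivot = pivot.reindex(subjects)
    return pivot.to_numpy()


def _stage_stats(config: PipelineConfig, force: bool) -> Path:
    mse_path = _require(config.out / "entropy" / "mse.tsv", "entropy")
    manifest_path = _require(config.out / "data" / "manifest.json", "simulate")
    stage_dir = config.out / "stats"
    params = {"stats": dict(config.stats), "bands": list(config.bands)}
    inputs = _input_digests([mse_path, manifest_path], config.out)
    if not force and _up_to_date(stage_dir, "stats", params, inputs):
        logger.info("stats: up to date, skipped")
        return stage_dir / "ancova.tsv"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tidy = read_tidy(mse_path)
    manifest = read_manifest(manifest_path)
    subs = manifest["subjects"]
    subjects = [s["subject_id"] for s in subs]
    design = pd.DataFrame({
        "group": [s["group"] for s in subs],
        "dz_use": [s.get("dz_use", False) for s in subs],
        "sex": [s.get("sex", "") for s in subs],
        "age": [s.get("age", float("nan")) for s in subs]})
    factors = tuple(config.stats.get("factors", ["group", "dz_use", "sex"]))
    covariates = tuple(config.stats.get("covariates", ["age"]))
    q = float(config.stats.get("q", 0.1))
    region_groups = config.stats.get("region_groups")
    if not region_groups:
        all_regions = sorted(tidy["region"].unique())
        region_groups = {f"r{r:02d}": [r] for r in all_regions}
    bonf = len(region_groups)
    hc_mask = design["group"].to_numpy() == "HC"

    ancova_rows, posthoc_rows = [], []
    for band in config.bands:
        sfs = band_scale_factors(band).factors
        for rg_name, regions in region_groups.items():
            spectral = _profile_matrix(tidy, subjects, regions, band,
                                       "spectral")
            res = rm_ancova(spectral, design, region=rg_name, band=band,
                            factors=factors, covariates=covariates,
                            bonferroni_factor=bonf)
            ancova_rows.append({
                "region": rg_name, "band": band,
                "p_group": res.p_group, "p_interaction": res.p_interaction,
                "p_group_raw": res.p_group_raw,
                "p_interaction_raw": res.p_interaction_raw,
                "gg_epsilon": res.gg_epsilon, "n_subjects": res.n_subjects})
            for component in ("spectral", "amplitude", "phase"):
                mat = _profile_matrix(tidy, subjects, regions, band, component)
                ph = posthoc_ttests(mat[hc_mask], mat[~hc_mask], sfs, q=q)
                for j, sf in enumerate(sfs):
                    posthoc_rows.append({
                        "region": rg_name, "band": band,
                        "component": component, "scale_factor": sf,
                        "t": ph.t[j], "p": ph.p[j],
                        "rejected": bool(ph.rejected[j]),
                        "direction": ph.direction[j]})
    write_tidy(stage_dir / "ancova.tsv", pd.DataFrame(ancova_rows))
    write_tidy(stage_dir / "posthoc.tsv", pd.DataFrame(posthoc_rows))

    # correlation maps + cognition correlations in the temporal group, alpha
    temporal = config.stats.get("region_groups", {}).get(
        "temporal", sorted(tidy["region"].unique())[:1])
    band = "alpha" if "alpha" in config.bands else config.bands[0]
    mats = {c: _profile_matrix(tidy, subjects, temporal, band, c)
            for c in ("spectral", "amplitude", "phase")}
    for a in ("spectral", "amplitude", "phase"):
        for b in ("spectral", "amplitude", "phase"):
            write_matrix(stage_dir / f"corrmap_{a}_{b}.tsv",
                         correlation_map(mats[a], mats[b]), fmt="%.6f")
    cog_rows = []
    sfs = band_scale_factors(band).factors
    mmse = np.array([s.get("mmse", np.nan) for s in subs], dtype=float)
    age = design["age"].to_numpy(float)
    for component, sf_idx, label in (("spectral", 2, "short"),
                                     ("spectral", 16, "long"),
                                     ("amplitude", 4, "short"),
                                     ("phase", 14, "long")):
        vals = mats[component][:, sf_idx]
        for score_name, score in (("mmse", mmse), ("age", age)):
            try:
                r, p = cognition_correlation(vals, score)
            except ValueError:
                r, p = float("nan"), float("nan")
            cog_rows.append({"component": component, "scale": label,
                             "scale_factor": sfs[sf_idx], "score": score_name,
                             "r": r, "p": p})
    write_tidy(stage_dir / "cognition.tsv", pd.DataFrame(cog_rows))
    _write_provenance(stage_dir, "stats", params, inputs)
    return stage_dir / "ancova.tsv"


def _features_from_tidy(tidy: pd.DataFrame, subjects: list[str],
                        band: str) -> np.ndarray:
    """(subjects, regions, 60) array: 3 components x 20 SFs per region."""
    regions = sorted(tidy["region"].unique())
    sfs = band_scale_factors(band).factors
    F = np.full((len(subjects), len(regions), 60), np.nan)
    sel = tidy[tidy["band"] == band]
    comp_order = {"spectral": 0, "amplitude": 1, "phase": 2}
    sf_order = {sf: i for i, sf in enumerate(sfs)}
    for row in sel.itertuples():
        si = subjects.index(row.subject)
        ri = regions.index(row.region)
        F[si, ri, comp_order[row.component] * 20 + sf_order[row.scale_factor]] \
            = row.sampen
    return F


def _stage_classify(config: PipelineConfig, force: bool) -> Path:
    mse_path = _require(config.out / "entropy" / "mse.tsv", "entropy")
    manifest_path = _require(config.out / "data" / "manifest.json", "simulate")
    stage_dir = config.out / "classify"
    params = {"classify": dict(config.classify), "seed": config.seed}
    inputs = _input_digests([mse_path, manifest_path], config.out)
    if not force and _up_to_date(stage_dir, "classify", params, inputs):
        logger.info("classify: up to date, skipped")
        return stage_dir / "report.json"
    stage_dir.mkdir(parents=True, exist_ok=True)
    tidy = read_tidy(mse_path)
    manifest = read_manifest(manifest_path)
    subjects = [s["subject_id"] for s in manifest["subjects"]]
    labels = np.array([s["group"] for s in manifest["subjects"]])
    band = config.classify.get("band",
                               "alpha" if "alpha" in config.bands
                               else config.bands[0])
    F = _features_from_tidy(tidy, subjects, band)
    cc = dict(config.classify)
    cc.pop("band", None)
    architectures = cc.pop("architectures", list(ARCHITECTURES))
    temporal = cc.pop("temporal_regions", None)
    if temporal is None:
        temporal = config.stats.get("region_groups", {}).get(
            "temporal", list(range(F.shape[1])))
    sae_kwargs = cc.pop("sae", {})
    cv = CVConfig(**cc, sae=SAEParams(**sae_kwargs), seed=config.seed)
    rng = np.random.default_rng(cv.seed)
    from neuromse.classifier import stratified_folds
    labels01 = (labels == "AD").astype(int)
    folds = np.stack([stratified_folds(labels01, cv.n_folds, rng)
                      for _ in range(cv.n_repeats)])
    report = {}
    for arch in architectures:
        rep = double_cv(F, labels, temporal, config=cv, architecture=arch,
                        fold_assignments=folds)
        report[arch] = rep.to_dict()
    (stage_dir / "report.json").write_text(json.dumps(report, indent=1))
    _write_provenance(stage_dir, "classify", params, inputs)
    return stage_dir / "report.json"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "decompose": _stage_decompose,
    "hsa": _stage_hsa,
    "entropy": _stage_entropy,
    "stats": _stage_stats,
    "classify": _stage_classify,
}


def run_stage(stage: str, config: PipelineConfig, force: bool = False) -> Path:
    """Run one named stage; returns its primary output path."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return _STAGE_FUNCS[stage](config, force)


def run_all(config: PipelineConfig, force: bool = False) -> dict[str, Path]:
    """Run every stage in order; skipping is per-stage via provenance."""
    return {stage: run_stage(stage, config, force) for stage in STAGES}
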