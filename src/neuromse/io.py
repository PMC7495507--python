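"""Plain-text file interfaces: TSV matrices, JSON manifests, tidy tables.

All numeric payloads are delimited text so every artifact of a run is
diffable and versionable; no binary neuroimaging formats are involved
(the pipeline starts downstream of source localization).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from neuromse.synthetic import Recording, SubjectManifest

__all__ = [
    "write_matrix", "read_matrix", "write_cohort", "read_manifest",
    "load_cohort", "write_tidy", "read_tidy", "sha256_of",
]

_MANIFEST_REQUIRED = ("subject_id", "group", "files")


def write_matrix(path: str | Path, matrix: np.ndarray,
                 fmt: str = "%.10g") -> None:
    """Write a 2-D array as TSV (rows x columns)."""
    np.savetxt(path, np.atleast_2d(matrix), delimiter="\t", fmt=fmt)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a TSV matrix; ragged rows raise with the offending line number."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                vals = [float(tok) for tok in line.split("\t")]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if rows and len(vals) != len(rows[0]):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(rows[0])} "
                    f"columns, found {len(vals)}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    return np.asarray(rows)


def write_cohort(recordings: list[Recording], manifests: list[SubjectManifest],
                 outdir: str | Path, fs: float | None = None) -> Path:
    """Write one TSV (regions x samples) per subject-segment plus a JSON
    manifest; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = []
    for rec, man in zip(recordings, manifests):
        files = []
        for seg in range(rec.n_segments):
            name = f"{rec.subject_id}_{seg:03d}.tsv"
            write_matrix(out / name, rec.data[seg])
            files.append(name)
        subjects.append({
            "subject_id": man.subject_id, "group": man.group,
            "age": man.age, "sex": man.sex, "dz_use": man.dz_use,
            "mmse": man.mmse, "wmsr_subscores": man.wmsr_subscores,
            "severity": man.severity, "amp_complexity": man.amp_complexity,
            "phase_diffusion": man.phase_diffusion, "files": files,
        })
    manifest = {
        "fs": recordings[0].fs if fs is None else fs,
        "n_regions": recordings[0].n_regions,
        "segment_samples": recordings[0].data.shape[2],
        "subjects": subjects,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path: str | Path) -> dict:
    """Load and validate a cohort manifest."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    if "subjects" not in manifest:
        raise ValueError(f"{path}: manifest missing field 'subjects'")
    for i, sub in enumerate(manifest["subjects"]):
        for fieldname in _MANIFEST_REQUIRED:
            if fieldname not in sub:
                raise ValueError(
                    f"{path}: subject entry {i} missing field {fieldname!r}")
    return manifest


def load_cohort(manifest_path: str | Path
                ) -> tuple[list[Recording], list[SubjectManifest]]:
    """Round-trip counterpart of :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    recordings, manifests = [], []
    for sub in manifest["subjects"]:
        segs = [read_matrix(root / f) for f in sub["files"]]
        data = np.stack(segs)
        recordings.append(Recording(subject_id=sub["subject_id"],
                                    fs=manifest["fs"], data=data))
        manifests.append(SubjectManifest(
            subject_id=sub["subject_id"], group=sub["group"],
            age=sub.get("age", float("nan")), sex=sub.get("sex", ""),
            dz_use=bool(sub.get("dz_use", False)),
            mmse=sub.get("mmse", 30.0),
            wmsr_subscores=sub.get("wmsr_subscores", {}),
            severity=sub.get("severity", 0.0),
            amp_complexity=sub.get("amp_complexity", 0.0),
            phase_diffusion=sub.get("phase_diffusion", 0.0)))
    return recordings, manifests


def write_tidy(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
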