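"""Session persistence: NIfTI volumes with JSON sidecars and a manifest.

A session directory contains:

* ``cest.nii`` — 4-D stack (x, y, offset, frame) with ``cest.json``
  carrying the acquisition protocol and frame times;
* ``wassr.nii`` + ``wassr.json`` — fine-offset water-reference stack;
* ``b1_rel.nii`` — relative-B1 map; ``mask.nii`` — integer muscle labels;
* ``truth.json`` — generator ground truth (when simulated);
* ``manifest.json`` — SHA-256 of every file plus seed and code version.

Coordinates are plain voxel indices (single-slice 2-D protocol); the
NIfTI affine is identity scaled by the in-plane resolution.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from crcest.phantom import CestStack, WassrStack, SimulatedSession
from crcest.protocol import AcquisitionProtocol

__all__ = ["save_session", "load_session", "write_manifest", "SessionError"]


class SessionError(RuntimeError):
    """Session directory is incomplete or inconsistent."""


def _affine(protocol: AcquisitionProtocol | None) -> np.ndarray:
    aff = np.eye(4)
    if protocol is not None:
        aff[0, 0] = protocol.fov_mm[0] / protocol.matrix[0]
        aff[1, 1] = protocol.fov_mm[1] / protocol.matrix[1]
    return aff


def _save_nifti(path: Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(directory: Path, extra: dict | None = None) -> dict:
    from crcest import __version__

    directory = Path(directory)
    files = sorted(
        p.name for p in directory.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "files": {name: _sha256(directory / name) for name in files},
    }
    if extra:
        manifest.update(extra)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def save_session(session: SimulatedSession, directory: str | Path) -> Path:
    """Write a simulated session to `directory` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    protocol = session.cest.protocol
    aff = _affine(protocol)

    _save_nifti(directory / "cest.nii", session.cest.data, aff)
    (directory / "cest.json").write_text(
        json.dumps(
            {
                "protocol": protocol.to_dict(),
                "frame_times_s": session.cest.frame_times_s.tolist(),
                "offsets_ppm": session.cest.offsets_ppm.tolist(),
                "units": "signal fraction of unsaturated water",
            },
            indent=2,
        )
    )
    _save_nifti(directory / "wassr.nii", session.wassr.data, aff)
    (directory / "wassr.json").write_text(
        json.dumps({"offsets_ppm": session.wassr.offsets_ppm.tolist()},
                   indent=2)
    )
    _save_nifti(directory / "b1_rel.nii", session.b1_rel_map, aff)
    _save_nifti(directory / "mask.nii",
                session.label_map.astype(np.int16), aff)
    (directory / "truth.json").write_text(
        json.dumps(session.ground_truth, indent=2)
    )
    write_manifest(directory, {"seed": session.ground_truth.get("seed")})
    return directory


def load_session(directory: str | Path) -> SimulatedSession:
    """Read a session directory back into in-memory containers."""
    directory = Path(directory)
    required = ["cest.nii", "cest.json", "wassr.nii", "wassr.json",
                "b1_rel.nii", "mask.nii"]
    missing = [f for f in required if not (directory / f).exists()]
    if missing:
        raise SessionError(
            f"session at {directory} is missing: {', '.join(missing)}"
        )
    cest_meta = json.loads((directory / "cest.json").read_text())
    protocol = AcquisitionProtocol.from_dict(cest_meta["protocol"])
    cest = CestStack(
        data=np.asanyarray(nib.load(str(directory / "cest.nii")).dataobj),
        protocol=protocol,
        frame_times_s=np.asarray(cest_meta["frame_times_s"]),
        offsets_ppm=np.asarray(cest_meta["offsets_ppm"]),
    )
    wassr_meta = json.loads((directory / "wassr.json").read_text())
    wassr = WassrStack(
        data=np.asanyarray(nib.load(str(directory / "wassr.nii")).dataobj),
        offsets_ppm=np.asarray(wassr_meta["offsets_ppm"]),
    )
    b1 = np.asanyarray(nib.load(str(directory / "b1_rel.nii")).dataobj)
    mask = np.asanyarray(nib.load(str(directory / "mask.nii")).dataobj)
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SimulatedSession(
        cest=cest,
        wassr=wassr,
        b1_rel_map=np.asarray(b1, dtype=float),
        label_map=np.asarray(mask).astype(np.int16),
        ground_truth=truth,
    )
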