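"""STAR-format metadata I/O: body definitions and per-particle pose tables.

The body-definition file holds one row per rigid body with its soft-mask
file, the body it rotates relative to, and the standard deviations of the
Gaussian priors on its residual rotations (degrees) and translations
(pixels).  Particle files carry a main ``data_images`` table with image
references, CTF parameters and consensus poses, plus one
``data_images_body_b`` table per body holding the residual poses.  Residual
Euler angles are serialized in the tilt-90 convention (a zero residual is
written as rot=0, tilt=90, psi=0); in memory the 90-degree offset is removed
so the identity residual is the zero pose.

Angles are degrees and offsets are pixels everywhere, in files and memory.
Parsing and writing go through gemmi's STAR/CIF machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .fourier import CTFParams
from .orientations import Pose

__all__ = [
    "BodySpec",
    "ParticleRecord",
    "StarFormatError",
    "read_body_star",
    "write_body_star",
    "read_particles_star",
    "write_particles_star",
    "assign_half_sets",
]


class StarFormatError(ValueError):
    pass


@dataclass
class BodySpec:
    """One row of the body-definition STAR file (1-based ordinals)."""

    body_index: int
    mask_path: str
    rotate_relative_to: int
    sigma_angles: float
    sigma_offset: float
    reference_path: str = ""

    def __post_init__(self):
        if self.sigma_angles < 0 or self.sigma_offset < 0:
            raise StarFormatError("prior standard deviations must be >= 0")

    @property
    def fixed(self) -> bool:
        """Bodies with zero prior widths keep their consensus placement."""
        return self.sigma_angles == 0.0 and self.sigma_offset == 0.0


@dataclass
class ParticleRecord:
    """One particle: image reference, CTF, consensus pose, per-body residuals."""

    image_ref: tuple[str, int]  # (stack path, 0-based slice index)
    ctf: CTFParams
    consensus_pose: Pose
    body_poses: list[Pose] = field(default_factory=list)
    half_set: int = 0
    pca_amplitudes: np.ndarray | None = None
    # posterior-mean residual poses (in-memory only; filled by the
    # refinement, lower-variance than the argmax poses stored above)
    body_pose_means: list[Pose] = field(default_factory=list)


_BODY_COLUMNS = [
    "_rlnBodyMaskName",
    "_rlnBodyRotateRelativeTo",
    "_rlnBodySigmaAngles",
    "_rlnBodySigmaOffset",
]

_PARTICLE_COLUMNS = [
    "_rlnImageName",
    "_rlnAngleRot",
    "_rlnAngleTilt",
    "_rlnAnglePsi",
    "_rlnOriginX",
    "_rlnOriginY",
]

_CTF_COLUMNS = [
    "_rlnDefocusU",
    "_rlnDefocusV",
    "_rlnDefocusAngle",
    "_rlnVoltage",
    "_rlnSphericalAberration",
    "_rlnAmplitudeContrast",
]


def _find_block(doc: gemmi.cif.Document, name: str) -> gemmi.cif.Block | None:
    for block in doc:
        if block.name == name:
            return block
    return None


def _table(block: gemmi.cif.Block, columns: list[str], context: str) -> list[list[str]]:
    for col in columns:
        if len(block.find_loop(col)) == 0:
            raise StarFormatError(f"{context}: missing mandatory column {col}")
    table = block.find(columns)
    return [[row[i] for i in range(len(columns))] for row in table]


def read_body_star(path) -> list[BodySpec]:
    """Read an ordered list of body definitions.

    File order matters: it sets the subtraction precedence (earlier bodies
    are subtracted first).  A missing rlnBodyReferenceName column leaves the
    initial reference empty.
    """
    doc = gemmi.cif.read_file(str(path))
    block = None
    for cand in doc:
        if len(cand.find_loop("_rlnBodyMaskName")) > 0:
            block = cand
            break
    if block is None:
        raise StarFormatError(f"{path}: no body table (missing column _rlnBodyMaskName)")
    rows = _table(block, _BODY_COLUMNS, str(path))
    has_ref = len(block.find_loop("_rlnBodyReferenceName")) > 0
    refs = list(block.find_loop("_rlnBodyReferenceName")) if has_ref else [""] * len(rows)
    specs = []
    for i, row in enumerate(rows):
        ref = refs[i]
        if ref in (".", "?", "None"):
            ref = ""
        specs.append(BodySpec(
            body_index=i + 1,
            mask_path=row[0],
            rotate_relative_to=int(row[1]),
            sigma_angles=float(row[2]),
            sigma_offset=float(row[3]),
            reference_path=ref,
        ))
    n = len(specs)
    for spec in specs:
        if not (1 <= spec.rotate_relative_to <= n):
            raise StarFormatError(
                f"body {spec.body_index}: rotate_relative_to={spec.rotate_relative_to} "
                f"does not refer to an existing body (1..{n})")
        if n > 1 and spec.rotate_relative_to == spec.body_index:
            raise StarFormatError(
                f"body {spec.body_index} cannot rotate relative to itself")
    return specs


def write_body_star(specs: list[BodySpec], path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("bodies")
    tags = [c.lstrip("_") for c in _BODY_COLUMNS]
    has_ref = any(s.reference_path for s in specs)
    if has_ref:
        tags.append("rlnBodyReferenceName")
    loop = block.init_loop("_", tags)
    for s in specs:
        row = [s.mask_path, str(s.rotate_relative_to),
               f"{s.sigma_angles:.6f}", f"{s.sigma_offset:.6f}"]
        if has_ref:
            row.append(s.reference_path or ".")
        loop.add_row(row)
    doc.write_file(str(path))


def _parse_image_ref(value: str) -> tuple[str, int]:
    if "@" in value:
        idx, stack = value.split("@", 1)
        return stack, int(idx) - 1
    return value, 0


def _format_image_ref(ref: tuple[str, int]) -> str:
    stack, idx = ref
    return f"{idx + 1:06d}@{stack}"


def read_particles_star(path) -> list[ParticleRecord]:
    """Read particle records with consensus poses and optional per-body tables.

    When ``data_images_body_b`` tables are present their residual poses are
    attached to the records (tilt de-offset by 90 degrees); otherwise every
    body pose starts at the identity residual.
    """
    doc = gemmi.cif.read_file(str(path))
    block = _find_block(doc, "images") or _find_block(doc, "particles")
    if block is None:
        for cand in doc:
            if len(cand.find_loop("_rlnImageName")) > 0 and "body" not in cand.name:
                block = cand
                break
    if block is None:
        raise StarFormatError(f"{path}: no particle table found")
    if all(len(block.find_loop(c)) == 0 for c in _PARTICLE_COLUMNS):
        return []  # valid empty table (loops with zero rows carry no columns)
    rows = _table(block, _PARTICLE_COLUMNS + _CTF_COLUMNS, str(path))
    half_col = list(block.find_loop("_rlnRandomSubset"))
    records = []
    for i, row in enumerate(rows):
        ctf = CTFParams(
            defocus_u=float(row[6]), defocus_v=float(row[7]),
            astig_angle=float(row[8]), voltage=float(row[9]),
            cs=float(row[10]), amplitude_contrast=float(row[11]),
        )
        pose = Pose(rot=float(row[1]), tilt=float(row[2]), psi=float(row[3]),
                    dx=float(row[4]), dy=float(row[5]))
        records.append(ParticleRecord(
            image_ref=_parse_image_ref(row[0]),
            ctf=ctf,
            consensus_pose=pose,
            half_set=int(half_col[i]) if half_col else 0,
        ))
    # per-body residual tables
    b = 1
    while True:
        body_block = _find_block(doc, f"images_body_{b}")
        if body_block is None:
            break
        body_rows = _table(body_block, _PARTICLE_COLUMNS[1:], f"{path} body {b}")
        if len(body_rows) != len(records):
            raise StarFormatError(
                f"{path}: body table {b} has {len(body_rows)} rows, "
                f"main table has {len(records)}")
        for rec, row in zip(records, body_rows):
            rec.body_poses.append(Pose(
                rot=float(row[0]), tilt=float(row[1]) - 90.0, psi=float(row[2]),
                dx=float(row[3]), dy=float(row[4])))
        b += 1
    n_bodies = b - 1
    if n_bodies == 0:
        pass  # consensus-only file; body poses added lazily by the refiner
    return records


def write_particles_star(records: list[ParticleRecord], path, extra_columns=None) -> None:
    """Write records as a main particle table plus one table per body.

    ``extra_columns`` is an optional mapping of column name -> per-record
    values appended to the main table (used e.g. for PCA amplitudes).
    """
    counts = {len(r.body_poses) for r in records}
    if len(counts) > 1:
        raise StarFormatError(f"heterogeneous body counts across records: {sorted(counts)}")
    n_bodies = counts.pop() if counts else 0
    doc = gemmi.cif.Document()
    block = doc.add_new_block("images")
    tags = [c.lstrip("_") for c in _PARTICLE_COLUMNS + _CTF_COLUMNS] + ["rlnRandomSubset"]
    extra_columns = extra_columns or {}
    tags += list(extra_columns)
    loop = block.init_loop("_", tags)
    for i, r in enumerate(records):
        p, c = r.consensus_pose, r.ctf
        row = [
            _format_image_ref(r.image_ref),
            f"{p.rot:.6f}", f"{p.tilt:.6f}", f"{p.psi:.6f}",
            f"{p.dx:.6f}", f"{p.dy:.6f}",
            f"{c.defocus_u:.2f}", f"{c.defocus_v:.2f}", f"{c.astig_angle:.6f}",
            f"{c.voltage:.2f}", f"{c.cs:.2f}", f"{c.amplitude_contrast:.4f}",
            str(r.half_set),
        ]
        for name in extra_columns:
            row.append(f"{extra_columns[name][i]:.6f}")
        loop.add_row(row)
    for b in range(n_bodies):
        bblock = doc.add_new_block(f"images_body_{b + 1}")
        btags = [c.lstrip("_") for c in _PARTICLE_COLUMNS[1:]]
        bloop = bblock.init_loop("_", btags)
        for r in records:
            bp = r.body_poses[b]
            bloop.add_row([
                f"{bp.rot:.6f}", f"{bp.tilt + 90.0:.6f}", f"{bp.psi:.6f}",
                f"{bp.dx:.6f}", f"{bp.dy:.6f}",
            ])
    doc.write_file(str(path))


def assign_half_sets(records: list[ParticleRecord], seed: int = 0) -> None:
    """Assign missing half-set labels by a seeded random equal split (in place)."""
    missing = [i for i, r in enumerate(records) if r.half_set not in (1, 2)]
    if not missing:
        return
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(missing))
    for rank, i in enumerate(perm):
        records[missing[i]].half_set = 1 if rank < len(missing) // 2 else 2
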