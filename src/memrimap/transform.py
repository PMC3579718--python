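"""12-parameter world-coordinate affine transforms.

A transform maps homogeneous world points (mm) from a source space to a
target space.  Throughout the pipeline the stored direction is
atlas -> subject: the transform carries atlas coordinates into each
subject's scan space, matching how subject-specific atlas copies are made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AffineTransform", "random_misalignment", "MisalignmentBounds"]


@dataclass
class AffineTransform:
    """Affine map ``x_target = A @ x_source + t`` in world mm.

    ``matrix`` is the full 4x4 homogeneous form; the 12 free parameters are
    its top three rows.  ``direction`` is metadata naming source->target.
    """

    matrix: np.ndarray
    direction: str = "atlas->subject"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape == (3, 4):
            m = np.vstack([m, [0.0, 0.0, 0.0, 1.0]])
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 3x4 or 4x4, got {m.shape}")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform linear part is singular")
        self.matrix = m

    @classmethod
    def identity(cls, direction: str = "atlas->subject") -> "AffineTransform":
        return cls(np.eye(4), direction=direction)

    @classmethod
    def from_params(
        cls,
        translation_mm=(0.0, 0.0, 0.0),
        rotation_deg=(0.0, 0.0, 0.0),
        scale=(1.0, 1.0, 1.0),
        shear=(0.0, 0.0, 0.0),
        center_mm=(0.0, 0.0, 0.0),
        direction: str = "atlas->subject",
    ) -> "AffineTransform":
        """Compose T * R * Sh * S about ``center_mm``.

        Rotations are extrinsic x, y, z in degrees; ``shear`` fills the
        (xy, xz, yz) upper-triangular entries.
        """
        rx, ry, rz = np.deg2rad(rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = shear
        L = Rz @ Ry @ Rx @ Sh @ np.diag(scale)
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float) + c - L @ c
        m = np.eye(4)
        m[:3, :3] = L
        m[:3, 3] = t
        return cls(m, direction=direction)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def params(self) -> np.ndarray:
        """The 12 free parameters, row-major over the top 3x4 block."""
        return self.matrix[:3, :].reshape(-1)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self∘other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix, direction=self.direction)

    def inverse(self) -> "AffineTransform":
        src, _, dst = self.direction.partition("->")
        return AffineTransform(
            np.linalg.inv(self.matrix), direction=f"{dst}->{src}" if dst else "inverse"
        )

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))

    # -- serialization: 12 numbers + a direction header ------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = [f"# direction: {self.direction}"]
        for row in self.matrix[:3]:
            lines.append(" ".join(f"{v:.17g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        text = Path(path).read_text().strip().splitlines()
        direction = "atlas->subject"
        rows = []
        for line in text:
            if line.startswith("#"):
                if "direction:" in line:
                    direction = line.split("direction:", 1)[1].strip()
                continue
            rows.append([float(v) for v in line.split()])
        m = np.asarray(rows, dtype=float)
        if m.shape != (3, 4):
            raise ValueError(f"{path}: expected 12 numbers in 3 rows, got {m.shape}")
        return cls(m, direction=direction)


@dataclass
class MisalignmentBounds:
    """Sampling bounds for random subject misalignments.

    Translations (uniform, ±mm) and rotations (uniform, ±deg) model head
    pose in the scanner; scale and shear (truncated normal, clipped at the
    bound) model modest anatomical size/shape variability — mouse whole
    brain volume varies by roughly 5% CV, so per-axis scale is drawn with
    a 3% SD rather than uniformly over the full ±10% range.
    """

    translation_mm: float = 1.0
    rotation_deg: float = 10.0
    scale: float = 0.10
    shear: float = 0.10
    scale_sd: float = 0.03
    shear_sd: float = 0.03


def random_misalignment(
    rng: np.random.Generator,
    bounds: MisalignmentBounds | None = None,
    center_mm=(0.0, 0.0, 0.0),
) -> AffineTransform:
    """Draw a subject misalignment within ``bounds`` about ``center_mm``."""
    b = bounds or MisalignmentBounds()
    t = rng.uniform(-b.translation_mm, b.translation_mm, size=3)
    r = rng.uniform(-b.rotation_deg, b.rotation_deg, size=3)
    s = np.clip(rng.normal(1.0, b.scale_sd, size=3), 1.0 - b.scale, 1.0 + b.scale)
    sh = np.clip(rng.normal(0.0, b.shear_sd, size=3), -b.shear, b.shear)
    return AffineTransform.from_params(
        translation_mm=t, rotation_deg=r, scale=s, shear=sh, center_mm=center_mm
    )
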