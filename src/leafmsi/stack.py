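"""Core in-memory containers for multispectral image stacks.

A stack is an ordered set of co-registered single-channel images, one per
LED band, together with a manifest mapping each band to its center
wavelength and a colour role (blue/green/red/nir).  Raw stacks hold sensor
counts; calibrated stacks hold unit-interval transmittance values plus a
per-pixel validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical role for each center wavelength used by the imager
ROLE_BY_WAVELENGTH = {405: "blue", 560: "green", 660: "red", 880: "nir"}

#: capture order of the device: NIR first, then red, green, blue
CAPTURE_ORDER_NM = (880, 660, 560, 405)


class FormatError(ValueError):
    """Raised when a stack or file does not satisfy the format contract."""


@dataclass
class BandInfo:
    """Manifest entry for one band."""

    wavelength_nm: float
    role: str

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise FormatError(f"wavelength must be positive, got {self.wavelength_nm}")
        if self.role not in {"blue", "green", "red", "nir"}:
            raise FormatError(f"unknown band role {self.role!r}")


def default_manifest() -> list[BandInfo]:
    """Manifest in device capture order (NIR, red, green, blue)."""
    return [BandInfo(wl, ROLE_BY_WAVELENGTH[wl]) for wl in CAPTURE_ORDER_NM]


@dataclass
class MultispectralStack:
    """Ordered per-band images sharing one shape, plus a band manifest.

    Parameters
    ----------
    data:
        Array of shape ``(n_bands, height, width)``.  Integer dtypes denote
        raw counts, floating dtypes calibrated/unit-interval values.
    manifest:
        One :class:`BandInfo` per band, in the same order as ``data``.
    """

    data: np.ndarray
    manifest: list[BandInfo] = field(default_factory=default_manifest)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"stack data must be 3-D (bands, H, W), got {self.data.ndim}-D")
        if len(self.manifest) != self.data.shape[0]:
            raise FormatError(
                f"manifest lists {len(self.manifest)} bands but stack has "
                f"{self.data.shape[0]} pages"
            )
        roles = [b.role for b in self.manifest]
        if len(set(roles)) != len(roles):
            raise FormatError(f"duplicate band roles in manifest: {roles}")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each band image."""
        return self.data.shape[1:]

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(b.wavelength_nm for b in self.manifest)

    def band_index(self, role: str) -> int:
        for i, b in enumerate(self.manifest):
            if b.role == role:
                return i
        raise FormatError(f"stack has no band with role {role!r}; has {[b.role for b in self.manifest]}")

    def band(self, role: str) -> np.ndarray:
        """The 2-D image for a colour role ('nir', 'red', 'green', 'blue')."""
        return self.data[self.band_index(role)]

    def same_geometry(self, other: "MultispectralStack") -> bool:
        """True if shapes and (wavelength, role) manifests agree in order."""
        return self.data.shape == other.data.shape and [
            (b.wavelength_nm, b.role) for b in self.manifest
        ] == [(b.wavelength_nm, b.role) for b in other.manifest]

    def copy(self) -> "MultispectralStack":
        return MultispectralStack(self.data.copy(), list(self.manifest))


@dataclass
class CalibratedStack(MultispectralStack):
    """Flat-field calibrated stack: values ~[0, 1], plus validity mask.

    ``valid`` marks pixels whose calibration denominator (white − dark) was
    usable in every band; invalid pixels hold 0 and must be excluded from
    statistics.
    """

    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1:], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape[1:]:
            raise FormatError("validity mask shape does not match band shape")

    def copy(self) -> "CalibratedStack":
        return CalibratedStack(self.data.copy(), list(self.manifest), self.valid.copy())
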