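"""File formats: HDF5 sinograms, TIFF/PNG slices, TIFF/NIfTI/HDF5 volumes,
YAML phantom descriptions.

The sinogram container is the interchange format between simulator and
reconstruction: dataset ``/sinogram`` (float32, angle x element x sample),
``/angles_deg``, ``/elements`` and root attributes carrying the sampling
rate, sound speed and ring geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .errors import ConfigurationError
from .geometry import RingGeometry
from .phantoms import Cuboid, Cylinder, Ellipsoid, Medium, Phantom, Reflector
from .reconstruct import SliceImage
from .simulate import Sinogram
from .volume import Volume

__all__ = [
    "write_sinogram",
    "read_sinogram",
    "write_slice",
    "read_slice",
    "write_volume",
    "phantom_from_dict",
    "phantom_to_dict",
]


def write_sinogram(path: str | Path, sinogram: Sinogram) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "sinogram", data=sinogram.ascans.astype(np.float32), compression="gzip"
        )
        f.create_dataset("angles_deg", data=np.asarray(sinogram.angles_deg))
        f.create_dataset("elements", data=np.asarray(sinogram.elements, dtype=np.int64))
        g = sinogram.geometry
        f.attrs["sampling_rate_hz"] = sinogram.sampling_rate_hz
        f.attrs["sound_speed_m_s"] = sinogram.medium.sound_speed_m_s
        f.attrs["ring_diameter_mm"] = g.ring_diameter_mm
        f.attrs["n_arrays"] = g.n_arrays
        f.attrs["n_elements"] = g.n_elements
        f.attrs["element_pitch_mm"] = g.element_pitch_mm
        if sinogram.interval_deg is not None:
            f.attrs["interval_deg"] = sinogram.interval_deg
        if sinogram.seed is not None:
            f.attrs["seed"] = sinogram.seed
    return path


def read_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["sinogram"], dtype=float)
        angles = np.asarray(f["angles_deg"], dtype=float)
        elements = tuple(int(e) for e in f["elements"][()])
        geom = RingGeometry(
            ring_diameter_mm=float(f.attrs["ring_diameter_mm"]),
            n_arrays=int(f.attrs.get("n_arrays", 4)),
            n_elements=int(f.attrs.get("n_elements", 128)),
            element_pitch_mm=float(f.attrs["element_pitch_mm"]),
        )
        return Sinogram(
            ascans=data,
            angles_deg=angles,
            elements=elements,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            geometry=geom,
            medium=Medium(sound_speed_m_s=float(f.attrs["sound_speed_m_s"])),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            interval_deg=(
                float(f.attrs["interval_deg"]) if "interval_deg" in f.attrs else None
            ),
        )


def write_slice(path: str | Path, image: SliceImage, png_preview: bool = False) -> Path:
    """32-bit float TIFF with physical pixel size and slice metadata in the
    image description; optional 8-bit PNG preview next to it."""
    path = Path(path)
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "element": image.element,
        "ring_radius_mm": image.ring_radius_mm,
        "dilation_radius_px": image.dilation_radius_px,
        "dynamic_range_db": image.dynamic_range_db,
    }
    px_per_cm = 10.0 / image.pixel_size_mm
    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        description=json.dumps(meta),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    if png_preview:
        import imageio.v3 as iio

        iio.imwrite(
            path.with_suffix(".png"),
            (np.clip(image.pixels, 0, 1) * 255).astype(np.uint8),
        )
    return path


def read_slice(path: str | Path) -> SliceImage:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        pixels = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return SliceImage(
        pixels=pixels,
        pixel_size_mm=float(meta.get("pixel_size_mm", 1.0)),
        element=int(meta.get("element", 1)),
        mask=np.ones_like(pixels, dtype=bool),
        ring_radius_mm=meta.get("ring_radius_mm"),
        dilation_radius_px=int(meta.get("dilation_radius_px", 0)),
        dynamic_range_db=meta.get("dynamic_range_db"),
    )


def write_volume(base_path: str | Path, volume: Volume) -> dict[str, Path]:
    """Export a volume as multi-page TIFF, NIfTI (voxel sizes in the header)
    and an HDF5 mirror; returns the written paths."""
    import nibabel as nib

    base = Path(base_path)
    paths: dict[str, Path] = {}

    tif = base.with_suffix(".tif")
    tifffile.imwrite(
        tif, volume.voxels.astype(np.float32), photometric="minisblack"
    )
    paths["tiff"] = tif

    affine = np.diag(
        [volume.pixel_size_mm, volume.pixel_size_mm, volume.slice_spacing_mm, 1.0]
    )
    # NIfTI convention: fastest axis first -> (col, row, slice)
    nii_data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32)
    nii = base.with_suffix(".nii")
    nib.save(nib.Nifti1Image(nii_data, affine), nii)
    paths["nifti"] = nii

    h5 = base.with_suffix(".h5")
    with h5py.File(h5, "w") as f:
        f.create_dataset("volume", data=volume.voxels.astype(np.float32))
        f.attrs["slice_spacing_mm"] = volume.slice_spacing_mm
        f.attrs["pixel_size_mm"] = volume.pixel_size_mm
        f.create_dataset("elements", data=np.asarray(volume.elements, dtype=np.int64))
    paths["hdf5"] = h5
    return paths


_REFLECTOR_TYPES = {"cylinder": Cylinder, "cuboid": Cuboid, "ellipsoid": Ellipsoid}


def phantom_from_dict(spec: dict) -> Phantom:
    """Build a phantom from a structured description (e.g. parsed YAML).

    Expected layout::

        medium: {sound_speed_m_s: 1540, ...}   # optional
        reflectors:
          - {type: cylinder, center_mm: [0,0,0], radius_mm: 10,
             height_mm: 60, reflectivity: 0.95}
          - {type: cuboid, center_mm: [...], edges_mm: [...], yaw_deg: 0, ...}
          - {type: ellipsoid, center_mm: [...], semi_axes_mm: [...], ...}
    """
    reflectors: list[Reflector] = []
    for i, r in enumerate(spec.get("reflectors", [])):
        r = dict(r)
        kind = r.pop("type", None)
        if kind not in _REFLECTOR_TYPES:
            raise ConfigurationError(
                f"phantom.reflectors[{i}].type: unknown reflector type {kind!r}"
            )
        for key in ("center_mm", "edges_mm", "semi_axes_mm"):
            if key in r:
                r[key] = tuple(float(v) for v in r[key])
        try:
            reflectors.append(_REFLECTOR_TYPES[kind](**r))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"phantom.reflectors[{i}]: {exc}") from exc
    medium = Medium(**spec.get("medium", {}))
    return Phantom(reflectors=tuple(reflectors), background=medium)


def phantom_to_dict(phantom: Phantom) -> dict:
    reflectors = []
    for r in phantom.reflectors:
        if isinstance(r, Cylinder):
            reflectors.append(
                {
                    "type": "cylinder",
                    "center_mm": list(r.center_mm),
                    "radius_mm": r.radius_mm,
                    "height_mm": r.height_mm,
                    "reflectivity": r.reflectivity,
                }
            )
        elif isinstance(r, Cuboid):
            reflectors.append(
                {
                    "type": "cuboid",
                    "center_mm": list(r.center_mm),
                    "edges_mm": list(r.edges_mm),
                    "yaw_deg": r.yaw_deg,
                    "reflectivity": r.reflectivity,
                }
            )
        elif isinstance(r, Ellipsoid):
            reflectors.append(
                {
                    "type": "ellipsoid",
                    "center_mm": list(r.center_mm),
                    "semi_axes_mm": list(r.semi_axes_mm),
                    "reflectivity": r.reflectivity,
                }
            )
        else:  # pragma: no cover
            raise ConfigurationError(f"cannot serialize reflector {type(r).__name__}")
    m = phantom.background
    return {
        "medium": {
            "sound_speed_m_s": m.sound_speed_m_s,
            "water_attenuation_db_cm_mhz": m.water_attenuation_db_cm_mhz,
            "tissue_attenuation_db_cm_mhz": m.tissue_attenuation_db_cm_mhz,
        },
        "reflectors": reflectors,
    }
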