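"""Synthetic head-CT phantom with crescent-shaped subdural collections.

The phantom emulates the kind of series the segmentation pipeline is meant
for: ~60 axial 512x512 slices of a head with an elliptical skull ring,
textured brain parenchyma, and one or two hyperdense crescents flush
against the inner skull table, plus a voxel-exact ground-truth mask and
per-series covariates (embolization flag, hematoma count).  Every stage of
the pipeline — preprocessing, training, inference, cross-validation,
volumetry — is trainable and testable on it without clinical data.

Lesion model
------------
Each crescent is defined in normalized elliptic coordinates.  With the
inner skull boundary mapped to the unit circle (``rho = 1``), a crescent
centred at polar angle ``theta0`` with angular half-width ``w`` occupies::

    1 - t(theta, z) <= rho < 1,   |theta - theta0| <= w

where the normalized depth ``t`` has a cosine profile across the arc and a
quadratic profile through the slices:

    t(theta, z) = tau(z) * cos(pi * (theta - theta0) / (2 w))
    tau(z)      = tau_max * max(0, 1 - ((z - z_c) / h)^2)

This shape is exactly volumable: the slice area in mm^2 is

    A(z) = a_in * b_in * (tau(z) * 4 w / pi - tau(z)^2 * w / 2)

with ``a_in``, ``b_in`` the inner-skull semi-axes in mm, so the analytic
series volume can be compared against the voxel-counted mask volume.

Intensities are abstract grayscale values (air 0, brain ~40, collection
~75, skull ~230), not calibrated Hounsfield units: the models consume
normalized grayscale slices, so calibration would add nothing testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CTVolume, MaskVolume, write_mask, write_series

__all__ = [
    "HUParams",
    "desk_spec",
    "PhantomSpec",
    "SeriesMeta",
    "Crescent",
    "SkullGeometry",
    "AnnotatedSeries",
    "generate_series",
    "generate_cohort",
    "paper_default_metas",
    "analytic_lesion_volume_ml",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class HUParams:
    """Mean/sd grayscale parameters per tissue class."""

    brain_mean: float = 40.0
    brain_sd: float = 3.0
    skull_mean: float = 230.0
    skull_sd: float = 12.0
    collection_mean: float = 75.0
    collection_sd: float = 4.0

    def validate(self) -> None:
        for name in ("brain_sd", "skull_sd", "collection_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"PhantomSpec.hu_params.{name} must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic series.

    ``image_size`` defaults to 512 (reducible for desk-scale tests),
    ``n_slices`` to 60 and ``slice_spacing_mm`` to 0.5, matching a typical
    thin-slice helical head acquisition.  ``max_thickness_mm`` is the peak
    crescent depth; 12 mm is a surgically relevant collection.
    """

    image_size: int = 512
    n_slices: int = 60
    pixel_spacing_mm: tuple[float, float] = (0.45, 0.45)
    slice_spacing_mm: float = 0.5
    hematoma_count: int = 1
    laterality: str = "left"  # left | right | bilateral
    max_thickness_mm: float = 12.0
    hu_params: HUParams = field(default_factory=HUParams)
    noise_sd: float = 2.0
    embolization: bool = False

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("PhantomSpec.image_size must be >= 16")
        if self.n_slices < 1:
            raise ValueError("PhantomSpec.n_slices must be >= 1")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("PhantomSpec.pixel_spacing_mm must be strictly positive")
        if self.slice_spacing_mm <= 0:
            raise ValueError("PhantomSpec.slice_spacing_mm must be strictly positive")
        if self.hematoma_count not in (1, 2):
            raise ValueError("PhantomSpec.hematoma_count must be 1 or 2")
        if self.laterality not in ("left", "right", "bilateral"):
            raise ValueError("PhantomSpec.laterality must be left, right or bilateral")
        if (self.hematoma_count == 2) != (self.laterality == "bilateral"):
            raise ValueError(
                "PhantomSpec.laterality must be 'bilateral' exactly when hematoma_count is 2"
            )
        if self.max_thickness_mm <= 0:
            raise ValueError("PhantomSpec.max_thickness_mm must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("PhantomSpec.noise_sd must be >= 0")
        self.hu_params.validate()


@dataclass(frozen=True)
class SeriesMeta:
    """Per-series covariates used for stratified cross-validation."""

    series_id: str
    patient_id: str
    embolization: bool
    hematoma_count: int

    def validate(self) -> None:
        if self.hematoma_count < 1:
            raise ValueError("SeriesMeta.hematoma_count must be >= 1")


@dataclass(frozen=True)
class Crescent:
    """Sampled geometry of one collection (normalized elliptic coordinates)."""

    theta0: float  # polar angle of the apex; 0 = right, pi = left
    half_width: float  # angular half-width w, radians
    peak_thickness_mm: float  # tau_max in mm at the apex
    center_slice: float  # z_c
    half_extent_slices: float  # h

    def thickness_mm(self, z: float | np.ndarray) -> np.ndarray:
        u = (np.asarray(z, dtype=float) - self.center_slice) / self.half_extent_slices
        return self.peak_thickness_mm * np.clip(1.0 - u * u, 0.0, None)


@dataclass(frozen=True)
class SkullGeometry:
    """Ellipse parameters of the skull ring in mm (image coordinates)."""

    center_mm: tuple[float, float]  # (y, x) of the ellipse centre
    inner_semi_axes_mm: tuple[float, float]  # (a_x, b_y) of inner table
    outer_semi_axes_mm: tuple[float, float]


@dataclass
class AnnotatedSeries:
    """A phantom volume with its ground-truth mask and covariates."""

    volume: CTVolume
    mask: MaskVolume
    meta: SeriesMeta
    lesions: tuple[Crescent, ...] = ()
    skull: SkullGeometry | None = None


def desk_spec(image_size: int = 64, n_slices: int = 10, **overrides) -> PhantomSpec:
    """A reduced-resolution spec with the same head geometry in mm.

    Scales the in-plane pixel spacing and inter-slice spacing so a 64x64,
    10-slice phantom covers the same field of view as the full 512x512,
    60-slice default — the head, skull and lesions keep their physical size.
    """
    ps = 0.45 * 512 / image_size
    return PhantomSpec(
        image_size=image_size,
        n_slices=n_slices,
        pixel_spacing_mm=(ps, ps),
        slice_spacing_mm=0.5 * 60 / n_slices,
        **overrides,
    )


# crescent voxels are only drawn where the local crescent thickness resolves
# to at least this many in-plane pixels; thinner regions (the angular tips of
# the arc and the first/last slices of the lesion) would rasterize into
# disconnected sub-pixel specks.  The analytic volume applies the identical
# truncation, so the two stay comparable at any resolution.
_MIN_THICKNESS_PX = 1.25


# ---------------------------------------------------------------------------
# single series


def _grids_mm(spec: PhantomSpec, center_mm):
    """Voxel-centre coordinates in mm relative to the skull centre."""
    n = spec.image_size
    ys = (np.arange(n) + 0.5) * spec.pixel_spacing_mm[0] - center_mm[0]
    xs = (np.arange(n) + 0.5) * spec.pixel_spacing_mm[1] - center_mm[1]
    return np.meshgrid(ys, xs, indexing="ij")


def generate_series(spec: PhantomSpec, seed: int) -> AnnotatedSeries:
    """Generate one synthetic series; identical (spec, seed) give identical output.

    The skull ring spans every slice (a cylindrical head: through-plane
    tapering is deliberately not modelled); crescents span a contiguous
    slice range around the middle of the stack.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    n = spec.image_size
    fov_y = n * spec.pixel_spacing_mm[0]
    fov_x = n * spec.pixel_spacing_mm[1]

    # skull ellipse: head occupies the central ~70-85% of the field of view
    # and always fits inside the 87.5% border crop used by preprocessing.
    cy = fov_y / 2 + rng.uniform(-0.01, 0.01) * fov_y
    cx = fov_x / 2 + rng.uniform(-0.01, 0.01) * fov_x
    ax_out = 0.34 * fov_x * rng.uniform(0.95, 1.05)
    by_out = 0.415 * fov_y * rng.uniform(0.95, 1.05)
    skull_mm = min(7.0, 0.12 * min(ax_out, by_out))
    ax_in, by_in = ax_out - skull_mm, by_out - skull_mm
    skull = SkullGeometry((cy, cx), (ax_in, by_in), (ax_out, by_out))
    if spec.max_thickness_mm >= 0.45 * ax_in:
        raise ValueError(
            "PhantomSpec.max_thickness_mm is too large for the head implied by "
            "image_size * pixel_spacing_mm; enlarge the field of view or use desk_spec()"
        )

    # lesion placement
    sides = {"left": [np.pi], "right": [0.0], "bilateral": [np.pi, 0.0]}[spec.laterality]
    zc = spec.n_slices * rng.uniform(0.45, 0.55)
    h = max(1.0, spec.n_slices * rng.uniform(0.28, 0.38))
    lesions = tuple(
        Crescent(
            theta0=theta0,
            half_width=rng.uniform(0.75, 1.1),
            peak_thickness_mm=spec.max_thickness_mm * rng.uniform(0.7, 1.0),
            center_slice=zc,
            half_extent_slices=h,
        )
        for theta0 in sides
    )

    yy, xx = _grids_mm(spec, (cy, cx))
    rho_in = np.sqrt((xx / ax_in) ** 2 + (yy / by_in) ** 2)
    rho_out = np.sqrt((xx / ax_out) ** 2 + (yy / by_out) ** 2)
    theta = np.arctan2(yy / by_in, xx / ax_in)

    brain2d = rho_in < 1.0
    skull2d = (rho_in >= 1.0) & (rho_out <= 1.0)

    hu = spec.hu_params
    base2d = np.zeros((n, n), dtype=np.float32)  # air
    base2d[skull2d] = hu.skull_mean
    base2d[brain2d] = hu.brain_mean

    nz = spec.n_slices
    volume = np.broadcast_to(base2d, (nz, n, n)).astype(np.float32).copy()
    mask = np.zeros((nz, n, n), dtype=np.uint8)

    for les in lesions:
        dtheta = np.angle(np.exp(1j * (theta - les.theta0)))
        in_arc = np.abs(dtheta) <= les.half_width
        profile = np.cos(np.pi * dtheta / (2 * les.half_width))
        # mm -> normalized depth via the radial scale at the apex (x axis)
        thick_mm = les.thickness_mm(np.arange(nz))
        tau = thick_mm / ax_in
        cutoff_norm = _MIN_THICKNESS_PX * max(spec.pixel_spacing_mm) / ax_in
        for z in range(nz):
            if tau[z] < cutoff_norm:
                continue
            t = tau[z] * profile
            cres = in_arc & (t >= cutoff_norm) & (rho_in < 1.0) & (rho_in >= 1.0 - t)
            mask[z][cres] = 1
            volume[z][cres] = hu.collection_mean

    # texture: per-tissue smooth random field scaled by the tissue sd
    sd2d = np.zeros((n, n), dtype=np.float32)
    sd2d[skull2d] = hu.skull_sd
    sd2d[brain2d] = hu.brain_sd
    sd_map = np.broadcast_to(sd2d, volume.shape).copy()
    sd_map[mask == 1] = hu.collection_sd
    if sd_map.any():
        tex = ndimage.gaussian_filter(rng.standard_normal(volume.shape), sigma=(0, 2, 2))
        s = tex.std()
        if s > 0:
            tex /= s
        volume += sd_map * tex.astype(np.float32)
    if spec.noise_sd > 0:
        volume += spec.noise_sd * rng.standard_normal(volume.shape).astype(np.float32)

    meta = SeriesMeta(
        series_id="s000",
        patient_id="p000",
        embolization=spec.embolization,
        hematoma_count=spec.hematoma_count,
    )
    geom = dict(pixel_spacing=spec.pixel_spacing_mm, slice_spacing=spec.slice_spacing_mm)
    return AnnotatedSeries(
        volume=CTVolume(volume, **geom),
        mask=MaskVolume(mask, **geom),
        meta=meta,
        lesions=lesions,
        skull=skull,
    )


def analytic_lesion_volume_ml(series: AnnotatedSeries) -> float:
    """Exact (continuous in-plane) volume of a series' crescents in mL.

    Sums the analytic per-slice area at the discrete slice positions used
    by the voxel mask, times the slice spacing; the voxel-counted mask
    volume converges to this as the in-plane resolution grows.

    With the thickness truncated at the sub-pixel cutoff ``c`` the crescent
    on a slice is ``{1 - t <= rho < 1, t >= c}`` with
    ``t = tau cos(pi (theta-theta0) / (2w))``, whose area in normalized
    coordinates has the closed form::

        A = tau (4w/pi) sin(beta) - (tau^2/2)(2w/pi)(beta + sin(beta)cos(beta)),
        beta = arccos(c / tau)

    scaled by ``a_in * b_in`` to mm^2 (``beta = pi/2`` recovers the
    untruncated crescent).
    """
    if series.skull is None:
        raise ValueError("series carries no phantom geometry")
    a_in, b_in = series.skull.inner_semi_axes_mm
    zs = np.arange(series.volume.n_slices)
    cutoff_norm = _MIN_THICKNESS_PX * max(series.volume.pixel_spacing) / a_in
    total_mm3 = 0.0
    for les in series.lesions:
        tau = les.thickness_mm(zs) / a_in
        w = les.half_width
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(tau >= cutoff_norm, np.arccos(np.minimum(cutoff_norm / np.where(tau > 0, tau, 1.0), 1.0)), 0.0)
        area = a_in * b_in * (
            tau * (4 * w / np.pi) * np.sin(beta)
            - (tau**2 / 2) * (2 * w / np.pi) * (beta + np.sin(beta) * np.cos(beta))
        )
        total_mm3 += float(area.sum() * series.volume.slice_spacing)
    return total_mm3 / 1000.0


# ---------------------------------------------------------------------------
# cohorts


def paper_default_metas() -> list[SeriesMeta]:
    """The 53-series default cohort composition.

    Marginals: 40 series with one hematoma and 13 with two; 26 with
    embolization and 27 without.  The joint split (7 embolized bilateral,
    19 embolized unilateral) and the patient composition (12 patients with
    3 series, 8 with 2, 1 with 1 — 21 patients) complete the marginals
    deterministically.
    """
    labels = (
        [(True, 2)] * 7 + [(False, 2)] * 6 + [(True, 1)] * 19 + [(False, 1)] * 21
    )
    patient_sizes = [3] * 12 + [2] * 8 + [1]
    patient_of_series: list[int] = []
    for p, size in enumerate(patient_sizes):
        patient_of_series += [p] * size
    return [
        SeriesMeta(
            series_id=f"s{i:03d}",
            patient_id=f"p{patient_of_series[i]:03d}",
            embolization=emb,
            hematoma_count=cnt,
        )
        for i, (emb, cnt) in enumerate(labels)
    ]


def _series_seed(master_seed: int, index: int) -> int:
    # deterministic per-series seed scheme: SeedSequence(master, index)
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def generate_cohort(
    n_series: int,
    covariate_table: list[SeriesMeta] | str | None = "paper_default",
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[AnnotatedSeries]:
    """Generate a cohort of annotated phantom series.

    ``covariate_table`` may be an explicit list of :class:`SeriesMeta`
    (length must equal ``n_series``), the string ``"paper_default"``
    (requires ``n_series == 53``), or ``None`` to draw covariates with the
    default cohort's proportions (13/53 bilateral, 26/53 embolized).
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0F0]))

    if covariate_table == "paper_default":
        metas = paper_default_metas()
        if n_series != len(metas):
            raise ValueError(
                f"paper_default covariate table has {len(metas)} series, got n_series={n_series}"
            )
    elif covariate_table is None:
        metas = [
            SeriesMeta(
                series_id=f"s{i:03d}",
                patient_id=f"p{i // 3:03d}",
                embolization=bool(rng.random() < 26 / 53),
                hematoma_count=2 if rng.random() < 13 / 53 else 1,
            )
            for i in range(n_series)
        ]
    else:
        if len(covariate_table) != n_series:
            raise ValueError(
                f"covariate_table has {len(covariate_table)} entries, expected {n_series}"
            )
        metas = list(covariate_table)

    cohort = []
    for i, meta in enumerate(metas):
        meta.validate()
        if meta.hematoma_count == 2:
            lat = "bilateral"
        else:
            lat = "left" if rng.random() < 0.5 else "right"
        spec_i = replace(
            base_spec,
            hematoma_count=meta.hematoma_count,
            laterality=lat,
            embolization=meta.embolization,
        )
        series = generate_series(spec_i, seed=_series_seed(seed, i))
        series.meta = meta
        cohort.append(series)
    return cohort


# ---------------------------------------------------------------------------
# on-disk cohorts


def write_cohort(
    cohort: list[AnnotatedSeries],
    directory: str | Path,
    format: str = "nifti",
    manifest_extra: dict | None = None,
) -> None:
    """Write volume+mask pairs, a covariate CSV and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii.gz", "archive": ".npz"}[format]
    rows = []
    for s in cohort:
        write_series(s.volume, directory / f"{s.meta.series_id}_ct{ext}", format=format)
        write_mask(s.mask, directory / f"{s.meta.series_id}_mask{ext}", format=format)
        rows.append(
            dict(
                series_id=s.meta.series_id,
                patient_id=s.meta.patient_id,
                embolization=s.meta.embolization,
                hematoma_count=s.meta.hematoma_count,
            )
        )
    pd.DataFrame(rows).to_csv(directory / "covariates.csv", index=False)
    manifest = {"format": format, "n_series": len(cohort)}
    manifest.update(manifest_extra or {})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cohort(directory: str | Path) -> list[AnnotatedSeries]:
    """Read back a cohort written by :func:`write_cohort`."""
    from .volume_io import read_mask, read_series

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    fmt = manifest["format"]
    ext = {"nifti": ".nii.gz", "archive": ".npz"}[fmt]
    table = pd.read_csv(directory / "covariates.csv")
    cohort = []
    for row in table.itertuples(index=False):
        meta = SeriesMeta(
            series_id=str(row.series_id),
            patient_id=str(row.patient_id),
            embolization=bool(row.embolization),
            hematoma_count=int(row.hematoma_count),
        )
        vol = read_series(directory / f"{meta.series_id}_ct{ext}", format=fmt)
        mask = read_mask(directory / f"{meta.series_id}_mask{ext}", format=fmt)
        cohort.append(AnnotatedSeries(volume=vol, mask=mask, meta=meta))
    return cohort
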