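"""Seeded multi-site synthetic head phantoms with exact ground-truth masks.

Each phantom is a geometric head: a brain ellipsoid (with mild smooth
internal texture), a surrounding skull shell, a fat layer outside the
skull, and two prominent eyes. Two modalities are rendered from one label
field — a T1-like image (fat bright, fluid/eyes dark) and a T2-like image
with the inverted brain/fluid contrast ordering — plus the exact binary
brain mask. Sites differ in volume dimensions, class intensities, noise
level and bias-field strength, emulating the variability of multi-center
MRI (field strength, coil, protocol) without any MR physics.

The "human-like" cohort (pretraining source domain) has a larger, rounder
brain with a thin skull and small eyes; the "macaque-like" cohort (target
domain) has a smaller, elongated brain, a thicker skull, more fat and
larger eyes, with stronger site-to-site intensity/noise scatter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import SpecError
from .volume_io import Volume, write_volume

TISSUES = ("background", "brain", "skull", "fat", "eye")

# Contrast orderings: on T1, fat is brightest and fluid (eyes) dark; on T2
# the fluid is brightest and fat intermediate, with brain below fluid.
DEFAULT_MEANS = {
    "t1": {"background": 0.02, "brain": 0.70, "skull": 0.15,
           "fat": 0.92, "eye": 0.25},
    "t2": {"background": 0.02, "brain": 0.45, "skull": 0.10,
           "fat": 0.60, "eye": 0.95},
}


@dataclass
class PhantomSpec:
    """Geometry and signal model for one synthetic head."""

    shape: tuple[int, int, int] = (64, 64, 48)
    brain_semiaxes: tuple[float, float, float] = (20.0, 24.0, 15.0)
    brain_center: tuple[float, float, float] | None = None
    skull_thickness: float = 3.0
    fat_thickness: float = 3.0
    eye_radius: float = 4.0
    eye_centers: tuple | None = None
    class_means: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in DEFAULT_MEANS.items()})
    noise_sd: float = 0.02
    bias_amplitude: float = 0.10
    bias_smoothness: float = 12.0
    texture_amplitude: float = 0.05
    field_tag: str = "3T"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.brain_center is None:
            self.brain_center = tuple(s / 2.0 for s in self.shape)
        if self.eye_centers is None:
            cx, cy, cz = self.brain_center
            ay = self.brain_semiaxes[1]
            # eyes sit anterior (along +y) of the brain, slightly lateral
            off = self.brain_semiaxes[0] * 0.45
            ey = min(cy + ay + self.eye_radius + 1.0,
                     self.shape[1] - self.eye_radius - 1.0)
            self.eye_centers = ((cx - off, ey, cz), (cx + off, ey, cz))
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise SpecError("noise_sd must be finite and >= 0")
        if self.bias_amplitude < 0 or not np.isfinite(self.bias_amplitude):
            raise SpecError("bias_amplitude must be finite and >= 0")
        for mod, means in self.class_means.items():
            if len(set(means.values())) != len(means):
                raise SpecError(f"class means for {mod} are not distinct")
        for c, a, s in zip(self.brain_center, self.brain_semiaxes, self.shape):
            if c - a < 0 or c + a > s:
                raise SpecError(
                    f"brain ellipsoid (center {self.brain_center}, semi-axes "
                    f"{self.brain_semiaxes}) exceeds volume bounds {self.shape}")

    def with_overrides(self, **kw) -> "PhantomSpec":
        d = dataclasses.asdict(self)
        d.update({k: v for k, v in kw.items() if v is not None})
        return PhantomSpec(**d)


@dataclass
class SiteProfile:
    """Per-site overrides of the base phantom spec."""

    site_id: str
    n_subjects: int = 2
    shape: tuple | None = None
    class_means: dict | None = None
    noise_sd: float | None = None
    bias_amplitude: float | None = None
    field_tag: str | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    gx, gy, gz = grid
    q = (((gx - center[0]) / semiaxes[0]) ** 2
         + ((gy - center[1]) / semiaxes[1]) ** 2
         + ((gz - center[2]) / semiaxes[2]) ** 2)
    return q <= 1.0


def _labels(spec: PhantomSpec) -> np.ndarray:
    grid = np.ogrid[0:spec.shape[0], 0:spec.shape[1], 0:spec.shape[2]]
    c, a = spec.brain_center, spec.brain_semiaxes
    brain = _ellipsoid(grid, c, a)
    skull_out = _ellipsoid(grid, c, tuple(x + spec.skull_thickness for x in a))
    fat_out = _ellipsoid(grid, c, tuple(
        x + spec.skull_thickness + spec.fat_thickness for x in a))
    lab = np.zeros(spec.shape, dtype=np.uint8)
    lab[fat_out] = TISSUES.index("fat")
    lab[skull_out] = TISSUES.index("skull")
    lab[brain] = TISSUES.index("brain")
    for ec in spec.eye_centers:
        eye = _ellipsoid(grid, ec, (spec.eye_radius,) * 3)
        lab[eye & ~brain] = TISSUES.index("eye")
    return lab


def _bias_field(shape, amplitude, smoothness,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, mean 1, excursion ~amplitude."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    g = gaussian_filter(rng.standard_normal(shape), smoothness)
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    return (1.0 + amplitude * g).astype(np.float32)


def _render(lab: np.ndarray, means: dict, spec: PhantomSpec,
            rng: np.random.Generator) -> np.ndarray:
    img = np.zeros(lab.shape, dtype=np.float32)
    for i, t in enumerate(TISSUES):
        img[lab == i] = means[t]
    if spec.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal(lab.shape), 3.0)
        sd = tex.std()
        if sd > 0:
            tex = tex / sd
        brain = lab == TISSUES.index("brain")
        img[brain] *= 1.0 + spec.texture_amplitude * tex[brain].astype(np.float32)
    img *= _bias_field(lab.shape, spec.bias_amplitude, spec.bias_smoothness, rng)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, lab.shape).astype(np.float32)
    return img.astype(np.float32)


def generate_phantom(spec: PhantomSpec, seed: int,
                     subject_id: str = "", site_id: str = ""
                     ) -> tuple[Volume, Volume, Volume]:
    """Render one subject: (t1, t2, mask), deterministic in seed."""
    lab = _labels(spec)
    # separate bias/noise draws per modality, both derived from one seed
    t1 = _render(lab, spec.class_means["t1"], spec, np.random.default_rng(
        np.random.SeedSequence([int(seed), 1])))
    t2 = _render(lab, spec.class_means["t2"], spec, np.random.default_rng(
        np.random.SeedSequence([int(seed), 2])))
    mask = (lab == TISSUES.index("brain")).astype(np.uint8)
    mk = dict(subject_id=subject_id, site_id=site_id)
    return (Volume(t1, modality="t1", **mk),
            Volume(t2, modality="t2", **mk),
            Volume(mask, modality="mask", **mk))


def degrade(volume: Volume, noise_sd: float, bias_amplitude: float,
            seed: int, bias_smoothness: float = 12.0) -> Volume:
    """Apply extra bias field and noise to an existing volume (mask untouched)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume intensities must be finite")
    rng = np.random.default_rng(seed)
    data = volume.data.astype(np.float32)
    data = data * _bias_field(data.shape, bias_amplitude, bias_smoothness, rng)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape).astype(np.float32)
    return Volume(data, affine=volume.affine, modality=volume.modality,
                  subject_id=volume.subject_id, site_id=volume.site_id)


# -- cohorts ---------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    site_id: str
    field_tag: str
    t1: Volume
    t2: Volume
    mask: Volume


def _rescale_spec(spec: PhantomSpec, shape) -> PhantomSpec:
    """Carry the anatomy over to a different volume shape by scaling the
    geometry with the per-axis grid ratio."""
    if shape is None or tuple(shape) == spec.shape:
        return spec
    shape = tuple(int(s) for s in shape)
    r = [shape[i] / spec.shape[i] for i in range(3)]
    rm = float(np.cbrt(r[0] * r[1] * r[2]))
    d = dataclasses.asdict(spec)
    d.update(shape=shape,
             brain_semiaxes=tuple(a * ri for a, ri in
                                  zip(spec.brain_semiaxes, r)),
             brain_center=tuple(c * ri for c, ri in
                                zip(spec.brain_center, r)),
             skull_thickness=spec.skull_thickness * rm,
             fat_thickness=spec.fat_thickness * rm,
             eye_radius=spec.eye_radius * rm,
             eye_centers=None)
    return PhantomSpec(**d)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Seeded per-subject anatomical variation (~10% in size, small shifts)."""
    semi = tuple(a * rng.uniform(0.90, 1.08) for a in spec.brain_semiaxes)
    center = tuple(c + rng.uniform(-1.5, 1.5) for c in spec.brain_center)
    eye_r = spec.eye_radius * rng.uniform(0.9, 1.1)
    d = dataclasses.asdict(spec)
    d.update(brain_semiaxes=semi, brain_center=center, eye_radius=eye_r,
             eye_centers=None)
    return PhantomSpec(**d)


def generate_cohort(profiles: list[SiteProfile], base: PhantomSpec, seed: int,
                    out_dir=None) -> list[SubjectRecord]:
    """Generate n_subjects phantoms per site with seeded per-subject jitter.

    If out_dir is given, writes NIfTI triplets plus a manifest.tsv with
    columns subject_id, site_id, field_tag and the three file paths.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    ids = [p.site_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise SpecError(f"duplicate site_ids in {ids}")
    records = []
    for si, prof in enumerate(profiles):
        site_spec = _rescale_spec(base, prof.shape).with_overrides(
            class_means=prof.class_means, noise_sd=prof.noise_sd,
            bias_amplitude=prof.bias_amplitude, field_tag=prof.field_tag)
        for sj in range(prof.n_subjects):
            ss = np.random.SeedSequence([int(seed), si, sj])
            jrng = np.random.default_rng(ss)
            spec = _jitter_spec(site_spec, jrng)
            sub_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            sid = f"{prof.site_id}_sub{sj:02d}"
            t1, t2, mask = generate_phantom(spec, sub_seed, subject_id=sid,
                                            site_id=prof.site_id)
            records.append(SubjectRecord(sid, prof.site_id,
                                         site_spec.field_tag, t1, t2, mask))
    if out_dir is not None:
        write_cohort(records, out_dir)
    return records


def write_cohort(records: list[SubjectRecord], out_dir) -> Path:
    import pandas as pd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        paths = {}
        for mod, vol in (("t1", r.t1), ("t2", r.t2), ("mask", r.mask)):
            p = out / f"{r.subject_id}_{mod}.nii.gz"
            write_volume(vol, p)
            paths[mod] = p.name
        rows.append({"subject_id": r.subject_id, "site_id": r.site_id,
                     "field_tag": r.field_tag, "t1": paths["t1"],
                     "t2": paths["t2"], "mask": paths["mask"]})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(data_dir) -> list[SubjectRecord]:
    """Read a cohort directory written by generate_cohort/write_cohort."""
    import pandas as pd
    from .volume_io import read_volume
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {data_dir}")
    df = pd.read_csv(manifest, sep="\t")
    records = []
    for _, row in df.iterrows():
        kw = dict(subject_id=row["subject_id"], site_id=row["site_id"])
        records.append(SubjectRecord(
            row["subject_id"], row["site_id"], row.get("field_tag", ""),
            read_volume(data_dir / row["t1"], "t1", **kw),
            read_volume(data_dir / row["t2"], "t2", **kw),
            read_volume(data_dir / row["mask"], "mask", **kw)))
    return records


# -- canned study profiles --------------------------------------------------

def human_profiles(n_sites: int = 2, n_subjects: int = 3) -> list[SiteProfile]:
    """Source-domain sites: big round brain, thin skull, small eyes."""
    tags = ["3T", "3T", "1.5T", "3T"]
    out = []
    for i in range(n_sites):
        out.append(SiteProfile(site_id=f"hum{i:02d}", n_subjects=n_subjects,
                               noise_sd=0.015 + 0.005 * (i % 2),
                               bias_amplitude=0.06 + 0.03 * (i % 2),
                               field_tag=tags[i % len(tags)]))
    return out


def human_base_spec(shape=(64, 64, 48)) -> PhantomSpec:
    s = tuple(shape)
    return PhantomSpec(
        shape=s,
        brain_semiaxes=(0.36 * s[0], 0.38 * s[1], 0.36 * s[2]),
        skull_thickness=2.0, fat_thickness=2.0,
        eye_radius=max(2.0, 0.04 * s[0]),
        texture_amplitude=0.04, field_tag="3T")


def macaque_base_spec(shape=(64, 64, 48)) -> PhantomSpec:
    # smaller, elongated brain; thicker skull and fat; prominent eyes
    s = tuple(shape)
    means = {
        "t1": {"background": 0.02, "brain": 0.62, "skull": 0.18,
               "fat": 0.88, "eye": 0.30},
        "t2": {"background": 0.02, "brain": 0.40, "skull": 0.12,
               "fat": 0.58, "eye": 0.92},
    }
    return PhantomSpec(
        shape=s,
        brain_semiaxes=(0.24 * s[0], 0.30 * s[1], 0.22 * s[2]),
        brain_center=(s[0] / 2.0, 0.44 * s[1], 0.52 * s[2]),
        skull_thickness=3.5, fat_thickness=3.5,
        eye_radius=max(3.0, 0.08 * s[0]),
        class_means=means, texture_amplitude=0.05, field_tag="3T")


def macaque_profiles(n_sites: int = 10,
                     n_subjects: int = 2) -> list[SiteProfile]:
    """Target-domain sites with per-site shape, contrast, noise and bias
    scatter (field-strength analogues 1.5T/3T/4.7T)."""
    shapes = [(64, 64, 48), (48, 64, 64), (64, 64, 64), (64, 48, 48),
              (56, 64, 48)]
    tags = ["1.5T", "3T", "4.7T"]
    out = []
    for i in range(n_sites):
        scale = 1.0 + 0.12 * ((i % 3) - 1)  # site-wise global contrast shift
        means = {mod: {t: v * scale for t, v in mm.items()}
                 for mod, mm in macaque_base_spec().class_means.items()}
        out.append(SiteProfile(
            site_id=f"mac{i:02d}", n_subjects=n_subjects,
            shape=shapes[i % len(shapes)], class_means=means,
            noise_sd=0.015 + 0.01 * (i % 3),
            bias_amplitude=0.05 + 0.05 * (i % 3),
            field_tag=tags[i % len(tags)]))
    return out
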