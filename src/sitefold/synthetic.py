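"""Synthetic multi-site histology cohorts with controllable batch effects.

The generator emulates the structure of a multi-site slide repository at
desk scale:

* **cohort tables** — per site, a configurable number of patients whose
  categorical outcome is drawn from a site-specific prevalence, so the
  site-outcome association (confounding) is dialable from none to
  deterministic;
* **tiles** — a minimal-but-learnable histology stand-in: elliptical dark
  "nuclei" blobs on a pink eosin-like background with Gaussian pixel noise.
  Class signal enters as a per-class multiplier on blob density; slide-level
  staining variability enters as a per-slide brightness jitter;
* **site stain signatures** — each site's tiles receive a multiplicative
  HSV shift (the same transform as the artificial stain artifact), at most
  a 5% increase per channel.

Every output is a pure function of (arguments, seed): randomness is drawn
from per-entity streams keyed by (seed, entity id), so growing a cohort
never perturbs existing slides, and a ground-truth log records every
generating parameter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .manifest import CATEGORICAL, CohortManifest, OutcomeColumn, SlideRecord
from .stain import scale_hsv
from .tiles import TileImage

__all__ = [
    "SiteProfile",
    "TextureParams",
    "Scenario",
    "generate_cohort",
    "render_tiles",
    "make_confounded_scenario",
]

#: Per-channel HSV multipliers outside this range are rejected by default
#: (the simulated site shift stays within a 0-10% band around identity).
HSV_SHIFT_RANGE = (0.90, 1.10)
#: Upper end of the simulated stain artifact: a 5% HSV increase.
MAX_ARTIFACT = 0.05


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-entity stream: seed sequence from (seed, crc32(keys))."""
    tags = [zlib.crc32(k.encode()) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


@dataclass
class SiteProfile:
    """Generating parameters of one tissue-submitting site."""

    site_id: str
    n_patients: int
    hsv_shift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    outcome_prevalence: dict[str, float] = field(default_factory=lambda: {"pos": 0.5, "neg": 0.5})
    enforce_shift_range: bool = True

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total = sum(self.outcome_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"site {self.site_id!r}: outcome prevalences sum to {total}, not 1"
            )
        if any(p < 0 for p in self.outcome_prevalence.values()):
            raise ValueError("prevalences must be non-negative")
        if self.enforce_shift_range:
            lo, hi = HSV_SHIFT_RANGE
            if any(not (lo <= f <= hi) for f in self.hsv_shift):
                raise ValueError(
                    f"hsv_shift {self.hsv_shift} outside [{lo}, {hi}]; "
                    "set enforce_shift_range=False to override"
                )


@dataclass
class TextureParams:
    """Parameters of the blob-on-background tile texture.

    ``blob_density`` is the expected blob count per tile; ``class_effect``
    multiplies it per outcome class, carrying the biologic (texture) signal.
    ``brightness_jitter`` and ``saturation_jitter`` are half-ranges of
    per-slide uniform multipliers on the HSV value and saturation channels,
    emulating slide-to-slide staining intensity variation.
    """

    blob_density: float = 25.0
    blob_radius_px: tuple[float, float] = (3.0, 1.0)  # mean, spread
    base_rgb: tuple[int, int, int] = (230, 180, 200)
    blob_rgb: tuple[int, int, int] = (110, 70, 160)
    class_effect: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 8.0
    noise_jitter: float = 0.05
    brightness_jitter: float = 0.02
    saturation_jitter: float = 0.0
    hue_jitter: float = 0.0
    tile_edge_px: int = 64

    def __post_init__(self) -> None:
        if self.blob_density <= 0:
            raise ValueError("blob_density must be positive")
        if self.blob_radius_px[0] <= 0 or self.blob_radius_px[1] < 0:
            raise ValueError("blob radius mean must be positive, spread non-negative")
        if any(m <= 0 for m in self.class_effect.values()):
            raise ValueError("class_effect multipliers must be positive")


def generate_cohort(
    profiles: Sequence[SiteProfile],
    slides_per_patient: int = 1,
    seed: int = 0,
    outcome_column: str = "outcome",
) -> CohortManifest:
    """Generate a cohort manifest from site profiles.

    Per site, exactly ``n_patients`` patients are created; each patient's
    outcome label is drawn from the site's prevalence using a stream keyed
    by (seed, patient id), so identical seeds give identical manifests.
    """
    if not profiles:
        raise ValueError("need at least one site profile")
    records = []
    for profile in profiles:
        classes = sorted(profile.outcome_prevalence)
        probs = np.array([profile.outcome_prevalence[c] for c in classes])
        for i in range(profile.n_patients):
            patient_id = f"{profile.site_id}-P{i:03d}"
            rng = _rng(seed, "label", patient_id)
            label = classes[int(rng.choice(len(classes), p=probs))]
            for j in range(slides_per_patient):
                records.append(
                    SlideRecord(
                        slide_id=f"{patient_id}-S{j}",
                        patient_id=patient_id,
                        site_id=profile.site_id,
                        outcomes={outcome_column: label},
                    )
                )
    return CohortManifest(records, [OutcomeColumn(outcome_column, CATEGORICAL)])


def _render_one_tile(
    rng: np.random.Generator,
    params: TextureParams,
    blob_multiplier: float,
    edge: Optional[int] = None,
) -> np.ndarray:
    """One unshifted tile; returns uint8 pixels. Blob count is Poisson."""
    pixels, _ = _render_one_tile_logged(rng, params, blob_multiplier, edge)
    return pixels


def _render_one_tile_logged(
    rng: np.random.Generator,
    params: TextureParams,
    blob_multiplier: float,
    edge: Optional[int] = None,
) -> tuple[np.ndarray, int]:
    e = edge or params.tile_edge_px
    pixels = np.empty((e, e, 3), dtype=np.float64)
    pixels[:] = params.base_rgb
    pixels += rng.normal(0.0, params.noise_sd, size=pixels.shape)

    n_blobs = int(rng.poisson(params.blob_density * blob_multiplier))
    mean_r, sd_r = params.blob_radius_px
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, e, size=2)
        a = max(0.8, rng.normal(mean_r, sd_r))
        b = max(0.8, rng.normal(mean_r, sd_r))
        theta = rng.uniform(0, np.pi)
        shade = rng.uniform(0.85, 1.15)
        r_lo, r_hi = int(max(0, cy - a - b)), int(min(e, cy + a + b + 1))
        c_lo, c_hi = int(max(0, cx - a - b)), int(min(e, cx + a + b + 1))
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dy, dx = yy - cy, xx - cx
        ct, st = np.cos(theta), np.sin(theta)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        inside = u * u + v * v <= 1.0
        for ch in range(3):
            block = pixels[r_lo:r_hi, c_lo:c_hi, ch]
            block[inside] = params.blob_rgb[ch] * shade
    return np.clip(np.rint(pixels), 0, 255).astype(np.uint8), n_blobs


def render_tiles(
    record: SlideRecord,
    profile: SiteProfile,
    texture: TextureParams,
    n_tiles: int,
    seed: int = 0,
    outcome_column: str = "outcome",
    with_log: bool = False,
):
    """Render a slide's tiles: class-dependent texture, then the site's HSV shift.

    The shift is applied with the same HSV transform as the artificial stain
    artifact.  All randomness comes from a stream keyed by (seed, slide id),
    so a (record, seed) pair always yields identical pixels.

    With ``with_log=True`` also returns a ground-truth dict (per-tile blob
    counts, the slide's brightness jitter, and the applied shift).
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    label = record.outcomes.get(outcome_column)
    mult = 1.0
    if texture.class_effect:
        if label not in texture.class_effect:
            raise ValueError(
                f"outcome class {label!r} not in class_effect {sorted(texture.class_effect)}"
            )
        mult = texture.class_effect[label]

    rng = _rng(seed, "tiles", record.slide_id)
    v_jitter = 1.0
    if texture.brightness_jitter > 0:
        v_jitter = float(rng.uniform(1 - texture.brightness_jitter, 1 + texture.brightness_jitter))
    s_jitter = 1.0
    if texture.saturation_jitter > 0:
        s_jitter = float(rng.uniform(1 - texture.saturation_jitter, 1 + texture.saturation_jitter))
    h_jitter = 1.0
    if texture.hue_jitter > 0:
        h_jitter = float(rng.uniform(1 - texture.hue_jitter, 1 + texture.hue_jitter))
    slide_texture = texture
    if texture.noise_jitter > 0:
        n_jitter = float(rng.uniform(1 - texture.noise_jitter, 1 + texture.noise_jitter))
        slide_texture = replace(texture, noise_sd=texture.noise_sd * n_jitter)

    tiles = []
    blob_counts = []
    factors = (
        profile.hsv_shift[0] * h_jitter,
        profile.hsv_shift[1] * s_jitter,
        profile.hsv_shift[2] * v_jitter,
    )
    identity = all(abs(f - 1.0) < 1e-15 for f in factors)
    for _t in range(n_tiles):
        pixels, n_blobs = _render_one_tile_logged(rng, slide_texture, mult)
        blob_counts.append(n_blobs)
        if not identity:
            pixels = scale_hsv(pixels, factors)
        tiles.append(
            TileImage(
                pixels=pixels,
                microns_per_pixel=1.0,
                origin=(0, 0),
                slide_id=record.slide_id,
            )
        )
    if with_log:
        log = {
            "slide_id": record.slide_id,
            "label": label,
            "blob_multiplier": mult,
            "blob_counts": blob_counts,
            "hsv_shift": tuple(profile.hsv_shift),
            "brightness_jitter": v_jitter,
            "saturation_jitter": s_jitter,
            "hue_jitter": h_jitter,
        }
        return tiles, log
    return tiles


@dataclass
class Scenario:
    """A confounded-cohort scenario plus its full generating ground truth."""

    manifest: CohortManifest
    profiles: dict[str, SiteProfile]
    texture: TextureParams
    ground_truth: dict
    seed: int
    outcome_column: str = "outcome"

    def tiles_for(self, record: SlideRecord, n_tiles: int, with_log: bool = False):
        return render_tiles(
            record,
            self.profiles[record.site_id],
            self.texture,
            n_tiles,
            self.seed,
            self.outcome_column,
            with_log=with_log,
        )


#: The eight corners of the unit HSV-shift cube, split by parity (number of
#: shifted channels).  Even-parity corners host one outcome class, odd-parity
#: corners the other: classes are then exactly balanced within every single
#: channel and every channel pair, so no low-order function of the stain
#: shift can predict the outcome — the site signature is memorizable but
#: carries no generalizable outcome signal.
_EVEN_CORNERS = [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)]
_ODD_CORNERS = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]


def _corner_shifts(
    n_sites: int, stain_strength: float, rng: np.random.Generator
) -> list[tuple[tuple[float, float, float], int]]:
    """Per-site HSV multipliers on the corners of the shift cube.

    Each site sits at a corner of {1, 1+0.05*strength}^3, alternating
    between even- and odd-parity corners (shuffled within parity by the
    seed), so neighboring signatures are maximally separated (a full 5%
    step per differing channel at strength 1) while corner parity — the
    site's latent class — stays balanced in every channel.  Beyond 8 sites
    corners repeat cyclically.  Returns (multipliers, parity) per site.
    """
    even = [tuple(_EVEN_CORNERS[i]) for i in rng.permutation(len(_EVEN_CORNERS))]
    odd = [tuple(_ODD_CORNERS[i]) for i in rng.permutation(len(_ODD_CORNERS))]
    amp = MAX_ARTIFACT * stain_strength
    out = []
    for j in range(n_sites):
        pool = even if j % 2 == 0 else odd
        corner = pool[(j // 2) % len(pool)]
        shift = tuple(1.0 + amp * c for c in corner)
        out.append((shift, j % 2))
    return out


def make_confounded_scenario(
    n_sites: int,
    confounding: float,
    stain_strength: float,
    seed: int,
    patients_per_site: int = 8,
    slides_per_patient: int = 1,
    texture: Optional[TextureParams] = None,
) -> Scenario:
    """Build a cohort whose outcome is confounded with site to a chosen degree.

    ``confounding`` interpolates the per-site outcome prevalence between
    independence (0: every site is 50/50) and determinism (1: a site's
    patients all share the site's latent class).  ``stain_strength`` scales
    each site's HSV shift linearly between identity and the 5% artifact
    ceiling.  Sites sit on the corners of the shift cube with the latent
    class given by corner parity, so at full confounding the outcome is
    memorizable from the stain signature but not predictable from any
    single channel or channel pair (see :func:`_corner_shifts`).
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if not (0.0 <= confounding <= 1.0):
        raise ValueError("confounding must lie in [0, 1]")
    if not (0.0 <= stain_strength <= 1.0):
        raise ValueError("stain_strength must lie in [0, 1]")

    shifts = _corner_shifts(n_sites, stain_strength, _rng(seed, "shifts"))
    profiles: dict[str, SiteProfile] = {}
    site_class: dict[str, str] = {}
    for j in range(n_sites):
        site_id = f"site{j:02d}"
        shift, parity = shifts[j]
        own = "pos" if parity == 0 else "neg"
        p_own = 0.5 + confounding / 2.0
        prevalence = {own: p_own, ("neg" if own == "pos" else "pos"): 1.0 - p_own}
        profiles[site_id] = SiteProfile(
            site_id=site_id,
            n_patients=patients_per_site,
            hsv_shift=shift,
            outcome_prevalence=prevalence,
        )
        site_class[site_id] = own

    manifest = generate_cohort(
        list(profiles.values()), slides_per_patient=slides_per_patient, seed=seed
    )
    texture = texture or TextureParams()
    ground_truth = {
        "n_sites": n_sites,
        "confounding": confounding,
        "stain_strength": stain_strength,
        "seed": seed,
        "patients_per_site": patients_per_site,
        "slides_per_patient": slides_per_patient,
        "site_class": site_class,
        "site_hsv_shift": {s: tuple(p.hsv_shift) for s, p in profiles.items()},
        "patient_label": {
            p: v for p, v in manifest.patient_outcome("outcome").items()
        },
        "texture": {
            "blob_density": texture.blob_density,
            "blob_radius_px": texture.blob_radius_px,
            "base_rgb": texture.base_rgb,
            "blob_rgb": texture.blob_rgb,
            "class_effect": dict(texture.class_effect),
            "noise_sd": texture.noise_sd,
            "brightness_jitter": texture.brightness_jitter,
            "tile_edge_px": texture.tile_edge_px,
        },
    }
    return Scenario(manifest, profiles, texture, ground_truth, seed)
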