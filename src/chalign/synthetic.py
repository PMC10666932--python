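"""Synthetic multi-subject cohorts with planted ground-truth misalignments.

The generator emulates the structure the alignment method assumes: a shared
latent "movie" signal with smooth spatial loadings on a template mesh, two
independently sampled movies that share the same spatial (hence
connectivity) structure, per-subject block-orthogonal misalignments of
local vertex space, and multi-run block-design localizers driven by smooth
category-tuning maps that are misaligned by the same transform.

Misalignment blocks are drawn uniformly on the orthogonal group of each
patch's vertex space restricted to the complement of the patch-constant
vector (``R 1 = 1``), so patch-mean (coarse-scale) topography is preserved
while fine-scale patterns are scrambled.  This is the favorable-case
geometry for hyperalignment: coarse anatomical correspondence holds, and
idiosyncrasy is confined to local orthogonal rotations — the hypothesis
class the method searches.  Fully Haar-random blocks (which also scramble
coarse structure) are available with ``preserve_patch_means=False``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import ortho_group

from .connectivity import TimeSeries
from .glm import Block, HRFSpec, LocalizerDesign, convolved_regressors
from .surface import (
    SurfaceMesh,
    apply_polar_cap_mask,
    build_icosphere,
    build_searchlight_set,
    geodesic_distances,
    n_icosphere_vertices,
)

DEFAULT_CATEGORIES = ("faces", "bodies", "scenes", "objects", "scrambled")


def child_rng(master_seed: int, *tags) -> np.random.Generator:
    """Deterministic child generator for (master seed, tag path).

    The tag path is hashed with CRC-32 so every (subject, condition, run)
    stream is reproducible independently of generation order.
    """
    digest = zlib.crc32("|".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), digest]))


# ---------------------------------------------------------------------------
# template

@dataclass
class TemplateModel:
    """Shared functional architecture: latent loadings and category tuning maps."""

    left_mesh: SurfaceMesh
    right_mesh: SurfaceMesh
    loadings: np.ndarray  # (V_total, n_latents), unit rows on cortex, 0 on mask
    tuning: np.ndarray  # (V_total, n_categories), standardized over cortex
    categories: list
    bump_width_mm: float
    seed: int

    @property
    def mesh_pair(self):
        return (self.left_mesh, self.right_mesh)

    @property
    def cortex_mask(self) -> np.ndarray:
        return np.concatenate([self.left_mesh.cortex_mask, self.right_mesh.cortex_mask])


def _bump_maps(
    mesh_pair, n_maps: int, bumps_per_map: int, bump_width_mm: float, rng
) -> np.ndarray:
    """Sums of spherical Gaussian bumps centered on random cortical vertices."""
    left, right = mesh_pair
    n_total = left.n_vertices + right.n_vertices
    out = np.zeros((n_total, n_maps))
    cortical = [(0, left, left.cortical_indices), (left.n_vertices, right, right.cortical_indices)]
    for j in range(n_maps):
        for _ in range(bumps_per_map):
            off, mesh, verts = cortical[rng.integers(2)]
            center = int(rng.choice(verts))
            amp = rng.standard_normal()
            d = geodesic_distances(mesh, [center])[0]
            out[off : off + mesh.n_vertices, j] += amp * np.exp(
                -(d**2) / (2.0 * bump_width_mm**2)
            )
    mask = np.concatenate([left.cortex_mask, right.cortex_mask])
    out[~mask] = 0.0
    return out


def make_template(
    mesh_pair,
    n_latents: int = 40,
    categories=DEFAULT_CATEGORIES,
    bump_width_mm: float = 10.0,
    bumps_per_map: int = 8,
    seed: int = 0,
) -> TemplateModel:
    """Draw smooth latent loadings and category tuning maps on the template mesh."""
    if n_latents < 2:
        raise ValueError("need at least 2 latents")
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    if bump_width_mm <= 0:
        raise ValueError("bump_width_mm must be positive")
    left, right = mesh_pair
    mask = np.concatenate([left.cortex_mask, right.cortex_mask])
    rng = child_rng(seed, "template", "loadings")
    loadings = _bump_maps(mesh_pair, n_latents, bumps_per_map, bump_width_mm, rng)
    # unit loading rows -> unit-variance template vertex courses
    norms = np.linalg.norm(loadings, axis=1, keepdims=True)
    loadings = np.divide(loadings, norms, out=np.zeros_like(loadings), where=norms > 0)
    # category tuning lives in the span of the latent loadings: category-selective
    # topography is part of the same functional architecture the movie drives,
    # which is what lets movie-derived alignment transfer to localizer contrasts
    rng = child_rng(seed, "template", "tuning")
    tuning = loadings @ rng.standard_normal((n_latents, len(categories)))
    mu = tuning[mask].mean(axis=0)
    sd = tuning[mask].std(axis=0)
    tuning[mask] = (tuning[mask] - mu) / np.where(sd == 0, 1.0, sd)
    return TemplateModel(
        left_mesh=left,
        right_mesh=right,
        loadings=loadings,
        tuning=tuning,
        categories=list(categories),
        bump_width_mm=bump_width_mm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# subjects

@dataclass
class SubjectGroundTruth:
    """Planted misalignment for one subject: a block-orthogonal vertex-space map."""

    subject_id: str
    patch_order: int
    patch_labels: dict  # hemisphere -> (V_h,) int array, -1 on masked vertices
    rotations: dict  # hemisphere -> csr (V_h, V_h), identity on masked vertices
    movie_noise_sd: float
    localizer_noise_sd: float
    seed: int

    def apply(self, template_data: np.ndarray, n_left: int) -> np.ndarray:
        """Rotate template-space (T, V) data into this subject's vertex space."""
        out = np.empty_like(template_data)
        out[:, :n_left] = template_data[:, :n_left] @ self.rotations["left"].T
        out[:, n_left:] = template_data[:, n_left:] @ self.rotations["right"].T
        return out


def _mean_preserving_orthogonal(n: int, rng) -> np.ndarray:
    """Haar-random orthogonal block restricted to fix the constant vector."""
    if n == 1:
        return np.ones((1, 1))
    basis = np.empty((n, n))
    basis[:, 0] = 1.0 / np.sqrt(n)
    basis[:, 1:] = rng.standard_normal((n, n - 1))
    q, _ = np.linalg.qr(basis)
    if q[:, 0] @ basis[:, 0] < 0:
        q = -q
    inner = ortho_group.rvs(n - 1, random_state=rng) if n > 2 else np.array([[rng.choice([-1.0, 1.0])]])
    return q @ sp.block_diag([np.ones((1, 1)), inner]).toarray() @ q.T


def make_subject(
    template: TemplateModel,
    subject_id: str,
    patch_order: int = 2,
    movie_noise_sd: float = 1.0,
    localizer_noise_sd: float = 50.0,
    seed: int = 0,
    preserve_patch_means: bool = True,
) -> SubjectGroundTruth:
    """Plant one random orthogonal block per nearest-coarse-center patch."""
    patch_labels: dict = {}
    rotations: dict = {}
    for hemi, mesh in zip(("left", "right"), template.mesh_pair):
        if patch_order >= mesh.subdivision_order:
            raise ValueError("patch_order must be below the mesh subdivision order")
        centers = np.arange(n_icosphere_vertices(patch_order))
        centers = centers[mesh.cortex_mask[centers]]
        cortical = mesh.cortical_indices
        d = geodesic_distances(mesh, centers)[:, cortical]
        nearest = np.argmin(d, axis=0)
        labels = np.full(mesh.n_vertices, -1, dtype=np.int64)
        labels[cortical] = nearest
        rng = child_rng(seed, subject_id, hemi, "rotations")
        mat = sp.identity(mesh.n_vertices, format="lil")
        for p in range(len(centers)):
            members = cortical[nearest == p]
            n = len(members)
            if n == 0:
                continue
            if preserve_patch_means:
                block = _mean_preserving_orthogonal(n, rng)
            else:
                block = ortho_group.rvs(n, random_state=rng) if n > 1 else np.ones((1, 1))
            mat[np.ix_(members, members)] = block
        patch_labels[hemi] = labels
        rotations[hemi] = mat.tocsr()
    return SubjectGroundTruth(
        subject_id=subject_id,
        patch_order=patch_order,
        patch_labels=patch_labels,
        rotations=rotations,
        movie_noise_sd=movie_noise_sd,
        localizer_noise_sd=localizer_noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# data simulation

def _ar1(n_timepoints: int, n_series: int, coeff: float, rng) -> np.ndarray:
    """Unit-marginal-variance AR(1) series, one per column."""
    if abs(coeff) >= 1:
        raise ValueError("AR(1) coefficient must satisfy |a| < 1")
    x = np.empty((n_timepoints, n_series))
    x[0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - coeff**2)
    eps = rng.standard_normal((n_timepoints - 1, n_series)) * innov_sd
    for t in range(1, n_timepoints):
        x[t] = coeff * x[t - 1] + eps[t - 1]
    return x


def _split_runs(n_timepoints: int, n_runs: int) -> list:
    base, extra = divmod(n_timepoints, n_runs)
    return [(f"run{k + 1}", base + (1 if k < extra else 0)) for k in range(n_runs)]


def simulate_movie(
    template: TemplateModel,
    subject: SubjectGroundTruth,
    movie_id: str,
    n_timepoints: int = 300,
    n_runs: int = 3,
    ar_coeff: float = 0.3,
    seed: int = 0,
    tr_s: float = 2.0,
) -> TimeSeries:
    """Simulate one subject's responses to one movie.

    Latent time courses are drawn independently per ``movie_id`` (different
    movies share spatial loadings but nothing temporal), projected through
    the loadings, rotated into the subject's vertex space, and degraded with
    white Gaussian noise.
    """
    if n_timepoints < 10:
        raise ValueError("movies need at least 10 timepoints")
    # the latent stimulus stream is shared by every subject watching this movie
    latent_rng = child_rng(seed, "movie-latents", movie_id)
    n_latents = template.loadings.shape[1]
    latents = _ar1(n_timepoints, n_latents, ar_coeff, latent_rng)
    z = latents @ template.loadings.T
    n_left = template.left_mesh.n_vertices
    data = subject.apply(z, n_left)
    if subject.movie_noise_sd > 0:
        noise_rng = child_rng(seed, subject.subject_id, "movie-noise", movie_id)
        data = data + subject.movie_noise_sd * noise_rng.standard_normal(data.shape)
    data[:, ~template.cortex_mask] = 0.0
    return TimeSeries(
        subject_id=subject.subject_id,
        condition_id=f"movie-{movie_id}",
        run_table=_split_runs(n_timepoints, n_runs),
        data=data,
        tr_s=tr_s,
    )


def simulate_localizer(
    template: TemplateModel,
    subject: SubjectGroundTruth,
    design: LocalizerDesign,
    hrf: HRFSpec,
    seed: int = 0,
    amplitude: float = 1.0,
) -> list:
    """Simulate block-design localizer runs (one TimeSeries per run).

    The template-space signal at vertex v is the tuning-weighted sum of the
    HRF-convolved category boxcars; each timepoint is then rotated by the
    subject's planted transform and white noise is added.
    """
    runs = []
    n_left = template.left_mesh.n_vertices
    for run_id in range(len(design.runs)):
        regs = convolved_regressors(design, run_id, hrf)
        z = amplitude * (regs @ template.tuning.T)
        data = subject.apply(z, n_left)
        rng = child_rng(seed, subject.subject_id, "localizer", run_id)
        if subject.localizer_noise_sd > 0:
            data = data + subject.localizer_noise_sd * rng.standard_normal(data.shape)
        data[:, ~template.cortex_mask] = 0.0
        runs.append(
            TimeSeries(
                subject_id=subject.subject_id,
                condition_id="localizer",
                run_table=[(f"run{run_id + 1}", design.n_timepoints[run_id])],
                data=data,
                tr_s=design.tr_s,
            )
        )
    return runs


def make_block_design(
    categories=DEFAULT_CATEGORIES,
    n_runs: int = 4,
    blocks_per_category: int = 2,
    block_duration_s: float = 18.0,
    gap_s: float = 4.0,
    lead_in_s: float = 12.0,
    tr_s: float = 2.0,
    seed: int = 0,
) -> LocalizerDesign:
    """A block-design localizer with per-run randomized category order."""
    runs = []
    n_timepoints = []
    for run_id in range(n_runs):
        rng = child_rng(seed, "design", run_id)
        order = list(categories) * blocks_per_category
        rng.shuffle(order)
        blocks = []
        t = lead_in_s
        for cat in order:
            blocks.append(Block(category=cat, onset_s=t, duration_s=block_duration_s))
            t += block_duration_s + gap_s
        run_len_s = t + lead_in_s - gap_s
        runs.append(blocks)
        n_timepoints.append(int(np.ceil(run_len_s / tr_s)))
    return LocalizerDesign(
        categories=list(categories), runs=runs, tr_s=tr_s, n_timepoints=n_timepoints
    )


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSpec:
    """Generation parameters; the defaults are the package's study conditions."""

    n_subjects: int = 10
    mesh_order: int = 3
    nominal_radius_mm: float = 100.0
    medial_wall_cap_deg: float = 20.0
    n_latents: int = 40
    categories: tuple = DEFAULT_CATEGORIES
    bump_width_mm: float = 10.0
    bumps_per_map: int = 8
    patch_order: int = 2
    preserve_patch_means: bool = True
    movie_timepoints: int = 300
    movie_runs: int = 3
    movie_ids: tuple = ("A", "B")
    ar_coeff: float = 0.3
    movie_noise_sd: float = 1.0
    localizer_noise_sd: float = 50.0
    localizer_amplitude: float = 1.0
    n_localizer_runs: int = 4
    blocks_per_category: int = 2
    block_duration_s: float = 18.0
    tr_s: float = 2.0


@dataclass
class CohortBundle:
    """A full synthetic cohort plus its ground truth and provenance manifest."""

    template: TemplateModel
    subjects: list  # [SubjectGroundTruth, ...]
    movies: dict  # (subject_id, movie_id) -> TimeSeries
    localizers: dict  # subject_id -> [TimeSeries, ...]
    design: LocalizerDesign
    hrf: HRFSpec
    spec: CohortSpec
    master_seed: int

    @property
    def mesh_pair(self):
        return self.template.mesh_pair

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.template.cortex_mask

    def manifest(self) -> dict:
        d = asdict(self.spec)
        d["categories"] = list(d["categories"])
        d["movie_ids"] = list(d["movie_ids"])
        return {"master_seed": self.master_seed, "spec": d}

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=2, sort_keys=True)


def make_cohort(spec: CohortSpec | None = None, master_seed: int = 0) -> CohortBundle:
    """Generate a complete cohort: template, subjects, two movies, localizers.

    Every RNG stream derives from ``(master_seed, subject, condition, run)``,
    so regeneration from the manifest is bitwise reproducible.
    """
    if spec is None:
        spec = CohortSpec()
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    meshes = []
    for hemi, axis in (("left", (1.0, 0.0, 0.0)), ("right", (-1.0, 0.0, 0.0))):
        mesh = build_icosphere(spec.mesh_order, spec.nominal_radius_mm, hemi)
        if spec.medial_wall_cap_deg:
            mesh = apply_polar_cap_mask(mesh, axis, spec.medial_wall_cap_deg)
        meshes.append(mesh)
    template = make_template(
        meshes,
        n_latents=spec.n_latents,
        categories=spec.categories,
        bump_width_mm=spec.bump_width_mm,
        bumps_per_map=spec.bumps_per_map,
        seed=master_seed,
    )
    design = make_block_design(
        categories=spec.categories,
        n_runs=spec.n_localizer_runs,
        blocks_per_category=spec.blocks_per_category,
        block_duration_s=spec.block_duration_s,
        tr_s=spec.tr_s,
        seed=master_seed,
    )
    hrf = HRFSpec()
    subjects, movies, localizers = [], {}, {}
    for k in range(spec.n_subjects):
        sid = f"sub-{k + 1:02d}"
        subj = make_subject(
            template,
            sid,
            patch_order=spec.patch_order,
            movie_noise_sd=spec.movie_noise_sd,
            localizer_noise_sd=spec.localizer_noise_sd,
            seed=master_seed,
            preserve_patch_means=spec.preserve_patch_means,
        )
        subjects.append(subj)
        for movie_id in spec.movie_ids:
            movies[(sid, movie_id)] = simulate_movie(
                template,
                subj,
                movie_id,
                n_timepoints=spec.movie_timepoints,
                n_runs=spec.movie_runs,
                ar_coeff=spec.ar_coeff,
                seed=master_seed,
                tr_s=spec.tr_s,
            )
        localizers[sid] = simulate_localizer(
            template, subj, design, hrf, seed=master_seed, amplitude=spec.localizer_amplitude
        )
    return CohortBundle(
        template=template,
        subjects=subjects,
        movies=movies,
        localizers=localizers,
        design=design,
        hrf=hrf,
        spec=spec,
        master_seed=master_seed,
    )
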