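"""Synthetic two-group connectome cohorts with known, controllable structure.

The generator emulates the statistical shape of mouse resting-state
functional connectomes without any imaging data:

* 90 bilaterally mirrored regions laid out on an anterior-posterior axis;
* modular correlation structure from a latent-factor model — each region's
  time series mixes its module's latent signal with Gaussian noise, and the
  module latents themselves are correlated (an anterior-posterior chain
  plus a posterior core module coupled to every module), so every subject
  matrix is a genuine Pearson correlation matrix by construction;
* heavy-tailed strength distribution via lognormal per-pair gain factors
  shared across subjects (the same regions are hubs in everyone);
* a disease effect that *attenuates* the anterior (prefrontal) module's
  coupling to the rest of the brain while *boosting* the posterior core
  module's internal coupling — weakened long-range anterior-posterior
  communication on top of a strengthened core.

All randomness is reproducible: per-subject seeds are derived by hashing
(cohort seed, group, subject index) through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ConnectivityMatrix, ConnectomeError, RegionAtlas

ANTERIOR_MODULE = 0  # prefrontal-like module, most anterior pairs
# the posterior core is always the last module (see CohortConfig)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for a synthetic two-group cohort.

    Defaults mirror a 90-region, 17-vs-17 design with 180 acquisition
    timepoints.  ``anterior_attenuation`` scales the disease group's
    anterior-module global coupling (0.3 = 70% weaker anterior-posterior
    communication); ``core_boost`` scales the disease group's core-module
    internal coupling.
    """

    n_regions: int = 90
    n_per_group: int = 17
    n_modules: int = 6
    base_coupling: float = 1.0
    cross_coupling: float = 0.55
    anterior_attenuation: float = 0.3
    core_boost: float = 1.4
    n_timepoints: int = 180
    noise_sd: float = 1.0
    gain_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions % 2 or self.n_regions < 4:
            raise ConnectomeError("n_regions must be even and >= 4")
        if not 0.0 <= self.anterior_attenuation <= 1.0:
            raise ConnectomeError("anterior_attenuation must lie in [0, 1]")
        if self.core_boost < 1.0:
            raise ConnectomeError("core_boost must be >= 1")
        if self.n_timepoints < 10:
            raise ConnectomeError("n_timepoints must be >= 10")
        if not 1 <= self.n_modules <= self.n_regions // 2:
            raise ConnectomeError("n_modules must be in [1, n_regions/2]")

    @property
    def core_module(self) -> int:
        """The posterior core module id (always the last module)."""
        return self.n_modules - 1

    def module_map(self) -> np.ndarray:
        """Region -> module assignment; bilateral partners share a module.

        Pairs are split into ``n_modules`` contiguous blocks along the
        anterior-posterior ordering: module 0 is the anterior prefrontal
        set, the last module the posterior core.
        """
        n_pairs = self.n_regions // 2
        pair_module = np.floor(
            np.arange(n_pairs) * self.n_modules / n_pairs
        ).astype(int)
        return np.repeat(pair_module, 2)


def generate_atlas(n_regions: int = 90, seed: int = 0) -> RegionAtlas:
    """Bilaterally mirrored atlas with an anterior->posterior y gradient.

    Regions come in L/R pairs (interleaved: pair p occupies indices 2p and
    2p+1) with mirrored x coordinates; y decreases from anterior (+ y) to
    posterior (- y); z carries small seeded jitter.
    """
    if n_regions % 2 or n_regions < 4:
        raise ConnectomeError("n_regions must be even and >= 4")
    rng = np.random.default_rng(seed)
    n_pairs = n_regions // 2
    y = np.linspace(6.0, -8.0, n_pairs)  # mm, anterior positive
    x_off = rng.uniform(1.0, 5.0, size=n_pairs)
    z = rng.uniform(-4.0, 4.0, size=n_pairs)
    labels, hemis, coords = [], [], []
    for p in range(n_pairs):
        for hemi, sign in (("L", -1.0), ("R", 1.0)):
            labels.append(f"Region{p:02d}_{hemi}")
            hemis.append(hemi)
            coords.append((sign * x_off[p], y[p], z[p]))
    return RegionAtlas(
        labels=tuple(labels), hemispheres=tuple(hemis), coords=np.array(coords)
    )


def _pair_gains(cfg: CohortConfig) -> np.ndarray:
    """Lognormal hub gains, shared by both hemispheres of a pair and by all
    subjects of a cohort (hub identity is population structure, not noise)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    gains = rng.lognormal(mean=0.0, sigma=cfg.gain_sigma, size=cfg.n_regions // 2)
    return np.repeat(gains, 2)


def _loadings(cfg: CohortConfig, group: str) -> np.ndarray:
    """Per-region loading onto the region's own module latent."""
    modules = cfg.module_map()
    a = cfg.base_coupling * _pair_gains(cfg)
    if group == "disease":
        a = np.where(modules == cfg.core_module, a * cfg.core_boost, a)
    elif group != "control":
        raise ConnectomeError(f"unknown group {group!r}")
    return a


def module_correlation(cfg: CohortConfig, group: str) -> np.ndarray:
    """Correlation matrix of the module latents.

    Adjacent modules along the anterior-posterior chain correlate at
    ``cross_coupling``; the posterior core module correlates with every
    other module at ``0.8 * cross_coupling`` (its hub role).  In the
    disease group the anterior module's couplings to all other modules are
    multiplied by ``anterior_attenuation``, severing anterior-posterior
    communication at the source.
    """
    k = cfg.n_modules
    m = np.eye(k)
    for c in range(k - 1):
        m[c, c + 1] = m[c + 1, c] = cfg.cross_coupling
    core = cfg.core_module
    for c in range(k):
        if c != core and abs(c - core) != 1:
            m[c, core] = m[core, c] = 0.8 * cfg.cross_coupling
    if group == "disease":
        ant = ANTERIOR_MODULE
        m[ant, :] *= cfg.anterior_attenuation
        m[:, ant] *= cfg.anterior_attenuation
        m[ant, ant] = 1.0
    return m


def _correlated_latents(
    corr: np.ndarray, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample (k, t) latent series with the given cross-correlation."""
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    return root @ rng.standard_normal((corr.shape[0], t))


def generate_subject_matrix(
    atlas: RegionAtlas, cfg: CohortConfig, group: str, seed: int
) -> ConnectivityMatrix:
    """One subject's raw Pearson correlation matrix from the latent model.

    Region i's series is ``a_i * L_{m(i)}(t) + noise``, with correlated
    module latents L (see :func:`module_correlation`) and iid Gaussian
    noise; the subject matrix is the pairwise Pearson correlation of these
    series with a zeroed diagonal.
    """
    if atlas.n_regions != cfg.n_regions:
        raise ConnectomeError("atlas size does not match the cohort config")
    rng = np.random.default_rng(seed)
    modules = cfg.module_map()
    a = _loadings(cfg, group)
    t = cfg.n_timepoints
    latents = _correlated_latents(module_correlation(cfg, group), t, rng)
    noise = rng.standard_normal((cfg.n_regions, t))
    series = a[:, None] * latents[modules] + cfg.noise_sd * noise
    corr = np.corrcoef(series)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(
        weights=corr,
        labels=atlas.labels,
        subject_id=f"{group}-s{seed}",
        group=group,
        state="raw",
    )


def subject_seed(cohort_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed hashed from (cohort seed, group, index)."""
    group_code = {"control": 1, "disease": 2}[group]
    ss = np.random.SeedSequence([cohort_seed, group_code, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[list[ConnectivityMatrix], list[ConnectivityMatrix], RegionAtlas]:
    """Full two-group cohort: (control subjects, disease subjects, atlas)."""
    atlas = generate_atlas(cfg.n_regions, seed=cfg.seed)
    control, disease = [], []
    for idx in range(cfg.n_per_group):
        control.append(
            generate_subject_matrix(
                atlas, cfg, "control", subject_seed(cfg.seed, "control", idx)
            )
        )
        disease.append(
            generate_subject_matrix(
                atlas, cfg, "disease", subject_seed(cfg.seed, "disease", idx)
            )
        )
    for group, ms in (("control", control), ("disease", disease)):
        for i, m in enumerate(ms):
            m.subject_id = f"{group}-{i:02d}"
    return control, disease, atlas
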