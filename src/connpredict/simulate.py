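"""Synthetic cohorts with the statistical structure the pipeline assumes.

No raw cohort ships with this package, so every stage is exercised on
simulated cohorts built to the target study shape: 58 subjects, a
198-ROI pool, 144 timepoints (6 minutes at TR 2.5 s), and integer 0-30
trait scores.

Generative model
----------------
Per subject, ROI time series are drawn from a zero-mean multivariate
normal whose target correlation matrix has ``rho_within`` inside each
canonical network block and ``rho_between`` elsewhere. A fixed set of
"informative" edges inside one designated network receives subject-
specific deviations delta_e ~ Normal(0, edge_sd^2); if a perturbed matrix
loses positive definiteness it is replaced by its nearest correlation
matrix (alternating projections). Series are then band-limited to the
0.01-0.1 Hz range characteristic of resting-state BOLD fluctuations by
frequency-domain masking.

The coupled trait subscale is built from the same deviations: a fixed
random weight vector w turns each subject's deltas into a standardized
latent score z = w . delta / (edge_sd * ||w||); the trait latent is
sqrt(effect_size) * z + sqrt(1 - effect_size) * noise_sd * eps plus a
sex term, then affinely mapped and rounded into the integer 0-30 range.
With ``noise_sd = 1`` the population R^2 between the edge deviations and
the (pre-rounding) trait equals ``effect_size`` exactly. The other three
subscales are edge-independent latents with subscale-typical means and
spreads. All randomness descends from one seed through a fixed
SeedSequence spawning scheme, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import NetworkDefinition, RoiSet, build_network, load_pool198
from .connectivity import SubjectTimecourses
from .exceptions import ConfigError, DataError, NumericError
from .traits import DEFAULT_ITEM_MAP, SUBSCALES, item_columns

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_item_responses",
    "generate_toy_volume",
    "band_limit",
    "nearest_correlation",
]

#: per-subscale (mean, sd) used for the affine map of latents to 0-30 scores
SUBSCALE_NORMS = {
    "FS": (19.7, 4.9),
    "EC": (23.6, 4.4),
    "PT": (20.4, 5.0),
    "PD": (14.2, 5.9),
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (defaults mirror the study shape)."""

    n_subjects: int = 58
    n_female: int = 30
    n_timepoints: int = 144          # 6 min at TR 2.5 s
    tr_seconds: float = 2.5
    band_hz: tuple[float, float] = (0.01, 0.1)
    rho_within: float = 0.3
    rho_between: float = 0.05
    informative_network: str = "dorsal_attention"
    n_informative_edges: int = 2
    edge_sd: float = 0.3             # between-subject sd of informative edges
    effect_size: float = 0.5         # population R^2 edge deviations -> trait
    coupled_subscale: str = "EC"
    sex_effect: float = 0.5          # standardized female-male trait difference
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ConfigError("need 0 <= rho_between <= rho_within < 1")
        if not (0 <= self.effect_size < 1):
            raise ConfigError("effect_size must lie in [0, 1)")
        if self.coupled_subscale not in SUBSCALES:
            raise ConfigError(f"unknown subscale {self.coupled_subscale!r}")
        if not (0 < self.n_female < self.n_subjects):
            raise ConfigError("both sexes must be represented")
        if self.n_timepoints < 8:
            raise ConfigError("need at least 8 timepoints")


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus its ground truth."""

    timecourses: list[SubjectTimecourses]
    true_edge_weights: np.ndarray            # (N, k) per-subject edge deviations
    true_informative_edges: list[tuple[str, str]]
    edge_weight_vector: np.ndarray           # fixed w, length k
    traits: pd.DataFrame                     # FS, EC, PT, PD integer scores
    sex: np.ndarray                          # 1 = female, 0 = male
    roi_labels: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def oracle_predictor(self) -> np.ndarray:
        """The noiseless linear predictor w . delta per subject."""
        return self.true_edge_weights @ self.edge_weight_vector

    @property
    def subjects(self) -> list[str]:
        return [tc.subject_id for tc in self.timecourses]


def band_limit(data: np.ndarray, tr_seconds: float, band_hz=(0.01, 0.1)) -> np.ndarray:
    """Zero all Fourier components outside [f_lo, f_hi] (rows = channels)."""
    T = data.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    mask = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not mask.any():
        raise ConfigError("pass band contains no resolvable frequencies")
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~mask] = 0.0
    return np.fft.irfft(spec, n=T, axis=-1)


def nearest_correlation(A: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    Y = np.array(A, dtype=float)
    dS = np.zeros_like(Y)
    for _ in range(max_iter):
        R = Y - dS
        w, Q = np.linalg.eigh((R + R.T) / 2)
        X = (Q * np.clip(w, 0, None)) @ Q.T
        dS = X - R
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, "fro") < tol * max(1.0, np.linalg.norm(Y, "fro")):
            Y = Y_new
            break
        Y = Y_new
    w_min = np.linalg.eigvalsh((Y + Y.T) / 2).min()
    if w_min < -1e-6:
        raise NumericError("nearest-correlation projection failed to converge")
    return (Y + Y.T) / 2


def _chol_psd(S: np.ndarray) -> np.ndarray:
    """Cholesky factor, with an eigenvalue-floor fallback for semidefinite S."""
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        w, Q = np.linalg.eigh(S)
        return Q * np.sqrt(np.clip(w, 1e-12, None))


def _base_correlation(networks_of: np.ndarray, rho_w: float, rho_b: float) -> np.ndarray:
    same = networks_of[:, None] == networks_of[None, :]
    S = np.where(same, rho_w, rho_b).astype(float)
    np.fill_diagonal(S, 1.0)
    return S


def generate_cohort(cfg: SimulationConfig, pool: RoiSet | None = None) -> SyntheticCohort:
    """Generate time courses, trait scores and sex labels for one cohort."""
    pool = pool if pool is not None else load_pool198()
    labels = pool.labels()
    net_labels = np.array([r.network for r in pool])
    if cfg.informative_network not in set(net_labels):
        raise ConfigError(
            f"informative network {cfg.informative_network!r} not in pool"
        )
    n_rois = len(labels)
    N, T = cfg.n_subjects, cfg.n_timepoints

    ss = np.random.SeedSequence(cfg.seed)
    s_edges, s_sex, s_traits, s_series = ss.spawn(4)

    # informative edges: ROI pairs inside the designated network, drawn in
    # the network's canonical ordering so labels match downstream features
    net = build_network(pool, cfg.informative_network)
    net_n = net.n
    n_pairs = net_n * (net_n - 1) // 2
    if cfg.n_informative_edges > n_pairs:
        raise ConfigError("more informative edges requested than network pairs")
    rng_e = np.random.default_rng(s_edges)
    pair_idx = rng_e.choice(n_pairs, size=cfg.n_informative_edges, replace=False)
    iu = np.triu_indices(net_n, k=1)
    net_lab = net.labels()
    edges = [(net_lab[iu[0][p]], net_lab[iu[1][p]]) for p in pair_idx]
    # unit-magnitude random-sign weights: every informative edge carries an
    # equal share (1/k) of the trait-relevant variance, so per-edge
    # detectability is a designed quantity rather than a lottery over draws
    w_vec = rng_e.choice([-1.0, 1.0], size=cfg.n_informative_edges)

    pos = {lab: i for i, lab in enumerate(labels)}
    edge_pool_idx = [(pos[a], pos[b]) for a, b in edges]

    # sex assignment: random permutation of 30 female / 28 male (by default)
    rng_s = np.random.default_rng(s_sex)
    sex = np.zeros(N, dtype=int)
    sex[rng_s.permutation(N)[: cfg.n_female]] = 1

    S0 = _base_correlation(net_labels, cfg.rho_within, cfg.rho_between)

    rng_t = np.random.default_rng(s_traits)
    delta = rng_t.normal(0.0, cfg.edge_sd, size=(N, cfg.n_informative_edges))

    subject_seeds = s_series.spawn(N)
    tcs = []
    for s in range(N):
        S = S0.copy()
        for (i, j), d in zip(edge_pool_idx, delta[s]):
            val = np.clip(S0[i, j] + d, -0.99, 0.99)
            S[i, j] = S[j, i] = val
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            S = nearest_correlation(S)
            L = _chol_psd(S)
        rng = np.random.default_rng(subject_seeds[s])
        Z = rng.standard_normal((T, n_rois))
        series = (Z @ L.T).T  # (n_rois, T)
        series = band_limit(series, cfg.tr_seconds, cfg.band_hz)
        tcs.append(SubjectTimecourses(f"sub-{s + 1:03d}", series, list(labels)))

    # traits: coupled subscale from the informative-edge deviations
    wnorm = np.linalg.norm(w_vec)
    z = (delta @ w_vec) / (cfg.edge_sd * wnorm)
    traits = {}
    for sub in SUBSCALES:
        mean, sd = SUBSCALE_NORMS[sub]
        eps = rng_t.standard_normal(N)
        if sub == cfg.coupled_subscale:
            latent = (
                np.sqrt(cfg.effect_size) * z
                + np.sqrt(1.0 - cfg.effect_size) * cfg.noise_sd * eps
                + cfg.sex_effect * (sex - sex.mean())
            )
        else:
            latent = eps
        traits[sub] = np.clip(np.rint(mean + sd * latent), 0, 30).astype(int)
    traits_df = pd.DataFrame(traits, index=[tc.subject_id for tc in tcs])
    traits_df["sex"] = sex

    prov = asdict(cfg)
    prov["band_hz"] = [float(b) for b in prov["band_hz"]]
    prov["pool_size"] = int(n_rois)
    prov["pool_networks"] = sorted(str(n) for n in set(net_labels))
    return SyntheticCohort(
        timecourses=tcs,
        true_edge_weights=delta,
        true_informative_edges=edges,
        edge_weight_vector=w_vec,
        traits=traits_df,
        sex=sex,
        roi_labels=list(labels),
        provenance=prov,
    )


def generate_item_responses(
    scores: pd.DataFrame,
    per_item_noise: float,
    seed: int,
    item_map: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Expand subscale scores into per-item 0-5 integer ratings.

    Each subscale score S is split into six base items (floor(S/6), with
    the remainder distributed one point at a time), then integer noise of
    scale `per_item_noise` is added and items are clipped to 0..5. With
    zero noise, re-scoring the items recovers the input totals exactly;
    growing noise progressively destroys inter-item consistency and hence
    Cronbach's alpha.
    """
    if per_item_noise < 0:
        raise ConfigError("per_item_noise must be >= 0")
    item_map = DEFAULT_ITEM_MAP if item_map is None else item_map
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=scores.index)
    for sub in SUBSCALES:
        S = np.asarray(scores[sub], dtype=int)
        if (S < 0).any() or (S > 30).any():
            raise DataError(f"{sub} scores outside 0..30")
        q, r = S // 6, S % 6
        cols = item_columns(item_map[sub])
        for j, col in enumerate(cols):
            base = q + (j < r)
            noisy = base + rng.normal(0.0, per_item_noise, size=len(S))
            out[col] = np.clip(np.rint(noisy), 0, 5).astype(int)
    if "sex" in scores.columns:
        out["sex"] = scores["sex"]
    return out[sorted(out.columns)]


def generate_toy_volume(
    rois: NetworkDefinition,
    n_timepoints: int,
    seed: int,
    voxel_mm: float = 4.0,
    margin_mm: float = 12.0,
    background_noise: float = 0.0,
    signal_corr: np.ndarray | None = None,
):
    """A small 4-D NIfTI fixture with a known signal inside each ROI sphere.

    The field of view is the bounding box of the ROI coordinates plus a
    margin, on an RAS mm affine. Each ROI's voxels carry one seeded signal
    (optionally with an imposed inter-ROI correlation structure); other
    voxels carry independent noise of sd `background_noise` (zero by
    default). Returns ``(image, ground_truth)`` where ground_truth has
    shape (n_rois, n_timepoints).
    """
    import nibabel as nib

    coords = rois.coordinates()
    lo = np.floor(coords.min(axis=0) - margin_mm)
    hi = np.ceil(coords.max(axis=0) + margin_mm)
    shape = np.maximum(np.ceil((hi - lo) / voxel_mm).astype(int) + 1, 2)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo

    rng = np.random.default_rng(seed)
    n = rois.n
    if signal_corr is None:
        signals = rng.standard_normal((n, n_timepoints))
    else:
        C = np.asarray(signal_corr, dtype=float)
        if C.shape != (n, n):
            raise ConfigError("signal_corr must be (n_rois, n_rois)")
        L = _chol_psd(C)
        signals = (rng.standard_normal((n_timepoints, n)) @ L.T).T

    data = np.zeros((*shape, n_timepoints))
    if background_noise > 0:
        data += rng.normal(0.0, background_noise, size=data.shape)

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1) * voxel_mm + lo
    for r_idx, roi in enumerate(rois.rois):
        d2 = np.sum((centers - roi.center) ** 2, axis=-1)
        mask = d2 <= roi.radius**2 + 1e-9
        if not mask.any():
            raise ConfigError(f"ROI {roi.label} sphere outside the field of view")
        data[mask] += signals[r_idx]
    return nib.Nifti1Image(data, affine), signals
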