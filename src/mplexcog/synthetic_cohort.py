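"""Synthetic multi-site cohorts with a planted cognition effect.

Generates paired structural/functional connectivity data, covariates and
a cognition z-score for an arbitrary number of subjects spread over
multiple acquisition sites.  The cognition score is a linear function of
age, gender and the *pipeline's own* multiplex frontoparietal eigenvector
centrality plus Gaussian noise — deliberately circular, so that
recovering the planted coefficient end-to-end exercises the whole
transform/spanning-tree/metric stack.

Site effects are additive constants applied to the connectivity weights
before the modality transforms; because spanning-tree construction is
invariant to strictly increasing transforms but not to per-site shifts
applied before ranking, this creates genuine (removable) site structure.

All randomness flows from one integer seed through per-subject,
per-purpose ``numpy`` seed sequences, so an identical configuration
yields a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import connectome_io, graph_layers, network_metrics
from .connectome_io import ConnectivityMatrix, Parcellation
from .exceptions import ConfigError, MplexcogError

#: The thirteen scan sites of the emulated multi-center cohort.
DEFAULT_SITES = (
    "Amsterdam",
    "Barcelona",
    "Basel",
    "Graz",
    "London",
    "Mainz",
    "Milan",
    "Naples",
    "Oslo",
    "Oxford",
    "Siena",
    "Vanvitelli",
    "Verona",
)

# substream tags, kept distinct per purpose
_STREAM_STRUCTURAL = 0
_STREAM_FUNCTIONAL = 1
_STREAM_COHORT = 2
_STREAM_NOISE = 3


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    n_regions: int = 114
    n_sites: int = 13
    site_effect_sd: float = 0.1
    structural_density: float = 0.6
    ts_length: int = 240
    age_range: tuple[float, float] = (18.0, 65.0)
    p_male: float = 0.31
    effect_coeffs: dict = dataclasses.field(
        default_factory=lambda: {
            "intercept": 0.4,
            "beta_age": -0.18,
            "beta_sex": -0.32,
            "beta_mplex_ecfpn": -0.117,
        }
    )
    noise_sd: float = 1.0
    fc_factor_loading: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_regions < 4:
            raise ConfigError("n_regions must be >= 4")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        lo = 2.0 / self.n_regions
        if not (lo <= self.structural_density <= 1.0):
            raise ConfigError(
                f"structural_density {self.structural_density} outside "
                f"[{lo:.4g}, 1]; a spanning tree needs density >= 2/n_regions"
            )
        if self.ts_length < 2:
            raise ConfigError("ts_length must be >= 2")
        if not (0.0 <= self.p_male <= 1.0):
            raise ConfigError("p_male must be a probability")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be (low, high) with low < high")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        missing = {
            "intercept", "beta_age", "beta_sex", "beta_mplex_ecfpn"
        } - set(self.effect_coeffs)
        if missing:
            raise ConfigError(f"effect_coeffs missing {sorted(missing)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return json.dumps(d, indent=2, sort_keys=True)


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    site: str
    age: float
    gender: int  # 0 = female, 1 = male
    sdmt_z: float
    edss: float | None = None
    mean_fd: float | None = None


@dataclasses.dataclass
class SyntheticCohort:
    config: CohortConfig
    manifest: pd.DataFrame
    matrices: dict  # subject_id -> {"structural": CM, "functional": CM}, raw
    metrics: pd.DataFrame  # subject_id + pipeline-computed ECfpn columns


def _rng(config: CohortConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(subject_index, stream))
    )


def _is_connected(weights: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(weights > 0), directed=False)
    return n_comp == 1


def generate_structural_matrix(
    config: CohortConfig, subject_index: int
) -> ConnectivityMatrix:
    """Sparse symmetric log-normal streamline-weight matrix.

    The number of nonzero upper-triangle entries equals
    ``round(structural_density * C(n, 2))`` exactly.  If the sampled edge
    set is disconnected after a bounded number of resamples, the edges of
    a random spanning tree are swapped in for the weakest sampled edges
    so sparsity is preserved.
    """
    n = config.n_regions
    n_pairs = n * (n - 1) // 2
    m = int(round(config.structural_density * n_pairs))
    if m < n - 1:
        raise ConfigError(
            f"structural_density {config.structural_density} gives {m} links; "
            f"a connected graph on {n} regions needs >= {n - 1}"
        )
    rng = _rng(config, subject_index, _STREAM_STRUCTURAL)
    iu, ju = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    for _attempt in range(5):
        pick = rng.choice(n_pairs, size=m, replace=False)
        vals = rng.lognormal(mean=0.0, sigma=1.0, size=m)
        w[:] = 0.0
        w[iu[pick], ju[pick]] = vals
        w += w.T
        if _is_connected(w):
            break
    else:
        # random recursive tree guarantees connectivity; drop the weakest
        # surplus links to keep the nonzero count at m
        perm = rng.permutation(n)
        for k in range(1, n):
            i, j = perm[k], perm[rng.integers(0, k)]
            if w[i, j] == 0:
                w[i, j] = w[j, i] = rng.lognormal(mean=0.0, sigma=1.0)
        ui, uj = np.triu_indices(n, k=1)
        nz = np.flatnonzero(w[ui, uj])
        excess = nz.size - m
        if excess > 0:
            order = nz[np.argsort(w[ui[nz], uj[nz]])]
            tree = {
                tuple(sorted(e))
                for e in graph_layers.maximum_spanning_tree(w).edges
            }
            removable = [
                k for k in order if (int(ui[k]), int(uj[k])) not in tree
            ][:excess]
            w[ui[removable], uj[removable]] = 0.0
            w[uj[removable], ui[removable]] = 0.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(f"sub-{subject_index:04d}", "structural", w, "raw")


def generate_functional_timeseries(
    config: CohortConfig, subject_index: int
) -> np.ndarray:
    """Region x time panel with latent-factor block structure.

    Regions load on ``min(7, n_regions // 3)`` latent factors (round
    robin) with loading ``fc_factor_loading``, plus unit Gaussian noise,
    so pairwise correlations show community blocks.  A loading of zero
    gives pure noise.
    """
    n, t = config.n_regions, config.ts_length
    if t < 2 * n:
        warnings.warn(
            f"ts_length {t} < 2 * n_regions {n}: correlation estimates will be noisy"
        )
    rng = _rng(config, subject_index, _STREAM_FUNCTIONAL)
    n_factors = max(1, min(7, n // 3))
    factors = rng.standard_normal((n_factors, t))
    assignment = np.arange(n) % n_factors
    panel = (
        config.fc_factor_loading * factors[assignment]
        + rng.standard_normal((n, t))
    )
    return panel


def _subject_multiplex_metrics(
    structural: ConnectivityMatrix,
    functional: ConnectivityMatrix,
    parcellation: Parcellation,
) -> dict:
    """Single-layer and multiplex FPN centrality via the real pipeline."""
    sc = connectome_io.preprocess_structural(structural)
    fc = connectome_io.preprocess_functional(functional)
    mst_s = graph_layers.maximum_spanning_tree(sc, "structural")
    mst_f = graph_layers.maximum_spanning_tree(fc, "functional")
    mplex = graph_layers.build_multiplex([mst_s, mst_f])
    ec_s = network_metrics.eigenvector_centrality(mst_s.adjacency)
    ec_f = network_metrics.eigenvector_centrality(mst_f.adjacency)
    ec_m = network_metrics.multilayer_nodal_ec(mplex)
    return {
        "ecfpn_structural": network_metrics.subnetwork_mean(
            ec_s, parcellation, "frontoparietal"
        ).mean,
        "ecfpn_functional": network_metrics.subnetwork_mean(
            ec_f, parcellation, "frontoparietal"
        ).mean,
        "ecfpn_multiplex": network_metrics.subnetwork_mean(
            ec_m, parcellation, "frontoparietal"
        ).mean,
    }


def site_labels(n_sites: int) -> tuple[str, ...]:
    """First ``n_sites`` of the default scan-site list, extended as needed."""
    if n_sites <= len(DEFAULT_SITES):
        return DEFAULT_SITES[:n_sites]
    extra = tuple(f"Site{k:02d}" for k in range(len(DEFAULT_SITES), n_sites))
    return DEFAULT_SITES + extra


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(
    config: CohortConfig,
    parcellation: Parcellation,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate manifest, matrix pairs and pipeline-computed ECfpn values.

    ``sdmt_z = intercept + beta_age * z(age) + beta_sex * gender
    + beta_mplex_ecfpn * z(multiplex ECfpn) + N(0, noise_sd)``,
    where the multiplex ECfpn is computed by the downstream transform +
    spanning-tree + centrality pipeline on each subject's own matrices.
    When ``out_dir`` is given, the manifest, per-subject matrix TSVs and
    a JSON sidecar echoing the configuration are written there.
    """
    if parcellation.n_regions != config.n_regions:
        raise ConfigError(
            f"parcellation has {parcellation.n_regions} regions, "
            f"config expects {config.n_regions}"
        )
    if parcellation.members("frontoparietal").size == 0:
        raise ConfigError("parcellation has no frontoparietal region")

    n = config.n_subjects
    rng = _rng(config, 0, _STREAM_COHORT)
    sites = site_labels(config.n_sites)
    site_idx = np.arange(n) % config.n_sites
    rng.shuffle(site_idx)
    site_offsets = rng.normal(0.0, config.site_effect_sd, size=config.n_sites)
    ages = rng.uniform(*config.age_range, size=n)
    gender = (rng.random(n) < config.p_male).astype(int)
    edss = rng.choice(np.arange(0.0, 7.5, 0.5), size=n)
    mean_fd = np.abs(rng.normal(0.10, 0.05, size=n))

    matrices: dict[str, dict[str, ConnectivityMatrix]] = {}
    metric_rows = []
    for s in range(n):
        sid = f"sub-{s:04d}"
        off = site_offsets[site_idx[s]]
        try:
            structural = generate_structural_matrix(config, s)
            w = structural.weights.copy()
            nz = w > 0
            w[nz] = np.maximum(w[nz] + off, 1e-6)
            structural = ConnectivityMatrix(sid, "structural", w, "raw")

            panel = generate_functional_timeseries(config, s)
            r = connectome_io.timeseries_to_correlation(panel)
            r = np.clip(r + off, -0.999, 0.999)
            r = (r + r.T) / 2.0
            np.fill_diagonal(r, 0.0)
            functional = ConnectivityMatrix(sid, "functional", r, "raw")

            metrics = _subject_multiplex_metrics(structural, functional, parcellation)
        except MplexcogError as exc:
            raise type(exc)(f"subject {sid}: {exc}") from exc
        matrices[sid] = {"structural": structural, "functional": functional}
        metric_rows.append({"subject_id": sid, **metrics})

    metrics_df = pd.DataFrame(metric_rows)
    coeffs = config.effect_coeffs
    noise = _rng(config, 0, _STREAM_NOISE).normal(0.0, config.noise_sd, size=n)
    sdmt_z = (
        coeffs["intercept"]
        + coeffs["beta_age"] * _zscore(ages)
        + coeffs["beta_sex"] * gender
        + coeffs["beta_mplex_ecfpn"]
        * _zscore(metrics_df["ecfpn_multiplex"].to_numpy())
        + noise
    )
    manifest = pd.DataFrame(
        {
            "subject_id": metrics_df["subject_id"],
            "site": [sites[k] for k in site_idx],
            "age": ages,
            "gender": gender,
            "sdmt_z": sdmt_z,
            "edss": edss,
            "mean_fd": mean_fd,
        }
    )
    cohort = SyntheticCohort(config, manifest, matrices, metrics_df)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    connectome_io.write_manifest(out / "manifest.tsv", cohort.manifest)
    (out / "config.json").write_text(cohort.config.to_json() + "\n")
    for sid, pair in cohort.matrices.items():
        for modality, cm in pair.items():
            connectome_io.write_matrix(out / f"{sid}_{modality}.tsv", cm)


def make_synthetic_parcellation(n_regions: int, name: str = "synthetic") -> Parcellation:
    """Round-robin assignment of regions to the 8 canonical networks."""
    nets = connectome_io.NETWORK_NAMES
    return Parcellation(
        name=name,
        labels=tuple(f"region_{i:03d}" for i in range(n_regions)),
        networks=tuple(nets[i % len(nets)] for i in range(n_regions)),
    )
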