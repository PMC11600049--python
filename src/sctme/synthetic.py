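"""Synthetic datasets with planted statistical structure and exposed truth.

Three generators mirror the three data modalities the analysis consumes:

* :func:`generate_dataset` — UMI counts over negative-binomial noise with
  cluster-specific marker elevation and group-dependent cluster composition
  (planted odds ratios).
* :func:`generate_cnv_profiles` — cell × window copy-number residuals with
  arm-level subclonal gains/losses on a toy genome.
* :func:`generate_survival_cohort` — exponential event times with a planted
  hazard ratio driven by a latent group that also elevates signature genes.

All generators are pure functions of (config, seed): the config carries the
seed and each generator derives an independent substream from it, so stages
never share random state.  Truth is returned alongside the data, never
embedded in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    CytobandTable,
    ExpressionDataset,
    ValidationError,
    VALID_GROUPS,
)

__all__ = [
    "ClusterSpec",
    "SimulationConfig",
    "SubcloneSpec",
    "CNVSimulationConfig",
    "SurvivalSimulationConfig",
    "generate_dataset",
    "generate_cnv_profiles",
    "generate_survival_cohort",
    "make_toy_genome",
]

# substream tags: one global seed feeds counter-based per-stage substreams
_STREAM_EXPR = 11
_STREAM_CNV = 23
_STREAM_SURV = 37

N_MITO_GENES = 10


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


@dataclass(frozen=True)
class ClusterSpec:
    """A planted cluster: its name, marker genes and their log2 elevation."""

    name: str
    marker_genes: tuple[str, ...] = ()
    marker_log2_shift: float = 0.0


@dataclass
class SimulationConfig:
    """Conditions for the expression generator.

    ``composition`` maps each group to a vector of expected cluster
    proportions (aligned with ``clusters``); each row must sum to 1.  Counts
    are negative binomial with per-gene means drawn log-normally around
    ``nb_mean`` and variance ``mean + mean**2 / nb_dispersion``.  The first
    :data:`N_MITO_GENES` genes of the universe carry the ``MT-`` prefix and
    are rescaled per cell so the expected mitochondrial share of counts is
    uniform over ``mito_fraction_range``.
    """

    n_genes: int = 200
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec("c0"),
        ClusterSpec("c1"),
    )
    composition: dict[str, Sequence[float]] = field(
        default_factory=lambda: {g: (0.5, 0.5) for g in VALID_GROUPS}
    )
    cells_per_sample: int = 500
    samples_per_group: int = 4
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    mito_fraction_range: tuple[float, float] = (0.02, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < N_MITO_GENES + 1:
            raise ValidationError(f"n_genes must exceed {N_MITO_GENES}")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be positive")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValidationError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate cluster names")
        for c in self.clusters:
            if c.marker_log2_shift < 0:
                raise ValidationError("marker shifts must be >= 0")
        for group, row in self.composition.items():
            if group not in VALID_GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            if len(row) != len(self.clusters):
                raise ValidationError("composition row length != number of clusters")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError(
                    f"composition row for {group!r} sums to {sum(row)}, not 1"
                )

    def gene_universe(self) -> list[str]:
        """Mito genes first, then planted markers, then filler genes."""
        markers: list[str] = []
        for c in self.clusters:
            for g in c.marker_genes:
                if g not in markers:
                    markers.append(g)
        mito = [f"MT-{i}" for i in range(N_MITO_GENES)]
        overlap = set(markers) & set(mito)
        if overlap:
            raise ValidationError(f"marker genes collide with mito names: {overlap}")
        n_fill = self.n_genes - N_MITO_GENES - len(markers)
        if n_fill < 0:
            raise ValidationError("n_genes too small for the requested markers")
        fill = [f"G{i:04d}" for i in range(n_fill)]
        return mito + markers + fill


def generate_dataset(config: SimulationConfig):
    """Draw an :class:`ExpressionDataset` plus a per-cell truth table.

    Returns ``(dataset, truth)`` where ``truth`` is a DataFrame with columns
    ``cell_id, sample_id, group, cluster``.  Deterministic for a fixed
    ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_EXPR)
    genes = config.gene_universe()
    n_genes = len(genes)
    cluster_names = [c.name for c in config.clusters]

    # per-gene baseline mean, log-normal around nb_mean
    base_mean = config.nb_mean * rng.lognormal(mean=0.0, sigma=0.5, size=n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    mito_idx = np.arange(N_MITO_GENES)
    nonmito = np.ones(n_genes, dtype=bool)
    nonmito[mito_idx] = False

    # per-cluster mean vectors (marker multiplier 2**shift)
    cluster_means = []
    for c in config.clusters:
        mu = base_mean.copy()
        for g in c.marker_genes:
            mu[gene_pos[g]] *= 2.0 ** c.marker_log2_shift
        cluster_means.append(mu)

    rows: list[np.ndarray] = []
    cell_ids: list[str] = []
    meta_rows: list[dict] = []
    theta = config.nb_dispersion
    for group in VALID_GROUPS:
        props = np.asarray(config.composition[group], dtype=float)
        for s in range(config.samples_per_group):
            sample_id = f"{group}_s{s}"
            n_per_cluster = rng.multinomial(config.cells_per_sample, props)
            for ci, n_c in enumerate(n_per_cluster):
                if n_c == 0:
                    continue
                mu = cluster_means[ci]
                # per-cell mito target fraction -> rescale MT- gene means
                f = rng.uniform(*config.mito_fraction_range, size=n_c)
                mu_block = np.broadcast_to(mu, (n_c, n_genes)).copy()
                e_nonmito = mu[nonmito].sum()
                e_mito = mu[mito_idx].sum()
                if e_mito > 0:
                    scale = (f / np.maximum(1 - f, 1e-12)) * e_nonmito / e_mito
                    mu_block[:, mito_idx] *= scale[:, None]
                # gamma-poisson mixture = negative binomial(mean, dispersion)
                lam = rng.gamma(shape=theta, scale=mu_block / theta)
                block = rng.poisson(lam)
                rows.append(block)
                start = len(cell_ids)
                for k in range(n_c):
                    cid = f"{sample_id}_c{start + k}"
                    cell_ids.append(cid)
                    meta_rows.append(
                        {
                            "cell_id": cid,
                            "sample_id": sample_id,
                            "group": group,
                            "cluster": cluster_names[ci],
                        }
                    )
    counts = sp.csr_matrix(np.vstack(rows)) if rows else sp.csr_matrix((0, n_genes))
    truth = pd.DataFrame(meta_rows, columns=["cell_id", "sample_id", "group", "cluster"])
    meta = truth.set_index("cell_id")
    dataset = ExpressionDataset(
        counts=counts, gene_ids=genes, cell_ids=cell_ids, meta=meta
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# CNV profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubcloneSpec:
    """A planted subclone: its arm events, cell fraction and signal size."""

    arm_events: frozenset  # of (chrom, arm, direction) with direction gain/loss
    fraction: float
    effect_size: float = 1.0


@dataclass
class CNVSimulationConfig:
    """Conditions for the copy-number residual generator.

    ``windows`` tile a toy genome; ``centromeres`` gives the p/q boundary per
    chromosome so planted arm events can be painted onto windows.  Subclone
    fractions refer to the ``n_cells`` tumour-compartment cells; any
    remainder stays diploid.  ``n_reference_cells`` diploid reference cells
    (noise only) are appended.
    """

    windows: tuple[tuple[str, int, int], ...]
    centromeres: dict[str, int]
    subclones: tuple[SubcloneSpec, ...]
    n_cells: int = 500
    noise_sd: float = 0.1
    n_reference_cells: int = 200
    seed: int = 0

    def validate(self) -> None:
        total = sum(s.fraction for s in self.subclones)
        if total > 1 + 1e-12:
            raise ValidationError(f"subclone fractions sum to {total} > 1")
        for s in self.subclones:
            if s.effect_size <= 0:
                raise ValidationError("effect_size must be > 0")
            if s.fraction < 0:
                raise ValidationError("fractions must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for chrom, start, end in self.windows:
            if chrom not in self.centromeres:
                raise ValidationError(f"no centromere for {chrom}")
            if end <= start:
                raise ValidationError(f"empty window {chrom}:{start}-{end}")


def make_toy_genome(
    n_chroms: int = 3,
    windows_per_arm: int = 10,
    window_size: int = 1_000_000,
):
    """Build windows, centromeres and a matching cytoband table for tests.

    Each toy chromosome has ``windows_per_arm`` windows on each arm; the
    centromere sits exactly between the arms.
    """
    windows: list[tuple[str, int, int]] = []
    centromeres: dict[str, int] = {}
    bands = []
    for c in range(1, n_chroms + 1):
        chrom = f"chr{c}"
        cen = windows_per_arm * window_size
        centromeres[chrom] = cen
        for w in range(2 * windows_per_arm):
            windows.append((chrom, w * window_size, (w + 1) * window_size))
        bands.append({"chrom": chrom, "start": 0, "end": cen, "band": "p11"})
        bands.append({"chrom": chrom, "start": cen, "end": 2 * cen, "band": "q11"})
    cyto = CytobandTable(pd.DataFrame(bands))
    return tuple(windows), centromeres, cyto


def _window_arm(window, centromeres) -> str:
    """Arm containing the majority of the window's span."""
    chrom, start, end = window
    cen = centromeres[chrom]
    p_overlap = max(0, min(end, cen) - start)
    q_overlap = max(0, end - max(start, cen))
    return "p" if p_overlap >= q_overlap else "q"


def generate_cnv_profiles(config: CNVSimulationConfig):
    """Draw a cell × window residual profile plus per-cell subclone truth.

    Reference cells get pure Normal(0, noise_sd) residuals; each subclone's
    cells additionally get ``+effect_size`` on every window of a gained arm
    and ``-effect_size`` on a lost arm.  Returns ``(profile, truth)`` where
    ``profile`` is a :class:`~sctme.cnv.CNVProfile` and ``truth`` a DataFrame
    with columns ``cell_id, subclone``.
    """
    from .cnv import CNVProfile  # local import to avoid a cycle

    config.validate()
    rng = _rng(config.seed, _STREAM_CNV)
    n_w = len(config.windows)
    arms = [_window_arm(w, config.centromeres) for w in config.windows]

    counts = [int(round(s.fraction * config.n_cells)) for s in config.subclones]
    n_diploid = config.n_cells - sum(counts)
    if n_diploid < 0:  # rounding overshoot
        counts[-1] += n_diploid
        n_diploid = 0

    cell_ids: list[str] = []
    labels: list[str] = []
    signal_rows: list[np.ndarray] = []
    for si, (spec, n_c) in enumerate(zip(config.subclones, counts)):
        signal = np.zeros(n_w)
        for chrom, arm, direction in spec.arm_events:
            sign = 1.0 if direction == "gain" else -1.0
            for wi, (w, a) in enumerate(zip(config.windows, arms)):
                if w[0] == chrom and a == arm:
                    signal[wi] += sign * spec.effect_size
        for k in range(n_c):
            cell_ids.append(f"sub{si}_c{k}")
            labels.append(f"subclone_{si}")
            signal_rows.append(signal)
    for k in range(n_diploid):
        cell_ids.append(f"dip_c{k}")
        labels.append("diploid")
        signal_rows.append(np.zeros(n_w))
    ref_ids = [f"ref_c{k}" for k in range(config.n_reference_cells)]
    for rid in ref_ids:
        cell_ids.append(rid)
        labels.append("reference")
        signal_rows.append(np.zeros(n_w))

    signal_mat = np.vstack(signal_rows) if signal_rows else np.zeros((0, n_w))
    noise = rng.normal(0.0, config.noise_sd, size=signal_mat.shape)
    residuals = signal_mat + noise
    profile = CNVProfile(
        residuals=residuals,
        windows=list(config.windows),
        cell_ids=cell_ids,
        reference_cell_ids=ref_ids,
    )
    truth = pd.DataFrame({"cell_id": cell_ids, "subclone": labels})
    return profile, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimulationConfig:
    """Conditions for the survival-cohort generator.

    Event times are exponential with hazard ``baseline_hazard *
    true_hr**z`` where the latent group ``z`` is Bernoulli(1/2) and also
    shifts the (log2-scale) signature-gene expression up by
    ``signature_shift``.  Censoring times are independent exponentials whose
    rate is solved so the expected censored fraction equals ``censor_rate``.
    """

    n_patients: int = 200
    baseline_hazard: float = 0.05
    true_hr: float = 1.5
    signature_genes: tuple[str, ...] = tuple(f"SIG{i}" for i in range(10))
    censor_rate: float = 0.2
    signature_shift: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        if self.baseline_hazard <= 0 or self.true_hr <= 0:
            raise ValidationError("hazards must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")
        if not self.signature_genes:
            raise ValidationError("signature_genes must be non-empty")


def _censoring_rate(h0: float, h1: float, target: float) -> float:
    """Exponential censoring rate giving expected censored fraction ``target``.

    Solves 0.5*c/(c+h0) + 0.5*c/(c+h1) = target for c >= 0 (quadratic).
    """
    if target <= 0:
        return 0.0
    r = target
    a = 1 - r
    b = (0.5 - r) * (h0 + h1)
    c0 = -r * h0 * h1
    disc = b * b - 4 * a * c0
    return (-b + math.sqrt(disc)) / (2 * a)


def generate_survival_cohort(config: SurvivalSimulationConfig) -> pd.DataFrame:
    """Draw a survival table with per-patient signature-gene expression.

    Returns a DataFrame with ``patient_id, time, event, true_group`` plus one
    linear-scale expression column per signature gene (``2**(5 + N(0,1) +
    shift*z)``, so the downstream log2 transform recovers a Gaussian).
    ``true_group`` is the latent hazard group (truth, not an input to the
    downstream stage).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_SURV)
    n = config.n_patients
    z = rng.integers(0, 2, size=n)
    hazard = config.baseline_hazard * config.true_hr ** z
    t_event = rng.exponential(1.0 / hazard)
    h0 = config.baseline_hazard
    h1 = config.baseline_hazard * config.true_hr
    c_rate = _censoring_rate(h0, h1, config.censor_rate)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "true_group": z,
        }
    )
    for g in config.signature_genes:
        log2_expr = 5.0 + rng.normal(size=n) + config.signature_shift * z
        df[g] = 2.0 ** log2_expr
    return df
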