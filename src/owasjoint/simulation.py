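"""Simulation study: openness-mediated phenotypes over synthetic LD blocks.

The generator stands in for a real genotyped cohort.  Per segment it draws

* an LD-structured diploid dosage matrix X (two haplotypes per individual
  from a latent AR(1) Gaussian copula thresholded at each SNP's MAF
  quantile),
* per-cell-type openness weight vectors W_l sharing a sparse support and
  correlated across the L cell types,
* openness scores O_l = X W_l and a quantitative phenotype
  y = sum_l lambda_l O_l + eps, with the noise SD chosen so the segment
  explains exactly the target heritability h2 in-sample.

A marginal GWAS on (y, X) produces the summary statistics the segment test
consumes; the simulated cohort doubles as its own LD reference panel.
``run_scenario`` evaluates five methods per segment -- the three
single-cell-type tests, their Bonferroni union, and the joint Cauchy
combination -- and reports power (or type-I error under the null
lambda = 0) averaged over replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .joint_acat import AcatWeights, acat
from .ld_reference import segment_ld
from .owas_single import segment_stat

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    Defaults emulate the study conditions: segments of 2-20 SNPs, common
    variants (MAF 0.05-0.5), moderate local LD (AR(1) rho = 0.5), three
    cell types whose openness effects correlate at 0.5, every SNP carrying
    an effect (deltaSVM scores are dense).
    """

    m_range: tuple[int, int] = (2, 20)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    n_cell_types: int = 3
    cross_ct_rho: float = 0.5
    sparsity: float = 1.0
    prune: bool = True
    r2_threshold: float = 0.99
    shrink: float | None = None  # None = analytic intensity; 0.0 disables


@dataclass
class SimScenario:
    """One simulation condition: effect sizes, heritability, and run sizes."""

    lambdas: tuple[float, float, float]
    h2: float
    n: int = 15_757
    n_segments: int = 500
    n_reps: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.is_null and self.h2 != 0.0:
            raise ValueError("null scenario (all lambdas 0) requires h2 = 0")
        if not self.is_null and self.h2 == 0.0:
            raise ValueError("h2 must be positive when any lambda is nonzero")

    @property
    def is_null(self) -> bool:
        return all(l == 0.0 for l in self.lambdas)

    @property
    def threshold(self) -> float:
        """Bonferroni rejection threshold over the tested segments."""
        return self.alpha / self.n_segments


#: the three causal-architecture settings: one, two, or three causal cell types
SETTING_LAMBDAS = {
    1: (1.0, 0.0, 0.0),
    2: (0.5, 0.5, 0.0),
    3: (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
}


@dataclass
class SimSegmentData:
    """Realized data for one simulated segment."""

    X: np.ndarray  # n x m dosages
    W: np.ndarray  # L x m openness weights
    O: np.ndarray  # n x L openness scores, O[:, l] = X @ W[l]
    y: np.ndarray
    noise_sd: float


@dataclass
class PowerReport:
    """Per-method rejection rates of one scenario, averaged over replicates."""

    methods: list[str]
    rates: np.ndarray  # mean rejection rate per method
    rates_sd: np.ndarray  # SD across replicates
    per_replicate: np.ndarray  # n_reps x n_methods
    scenario: SimScenario
    threshold: float
    p_single: np.ndarray | None = None  # pooled per-test p, n_tests x L
    p_joint: np.ndarray | None = None

    def rate(self, method: str) -> float:
        return float(self.rates[self.methods.index(method)])

    def to_dict(self) -> dict:
        d = {
            "scenario": asdict(self.scenario),
            "threshold": self.threshold,
            "methods": self.methods,
            "rates": self.rates.tolist(),
            "rates_sd": self.rates_sd.tolist(),
            "per_replicate": self.per_replicate.tolist(),
        }
        return d


def simulate_genotype_block(
    n: int,
    m: int,
    mafs: np.ndarray | float,
    ld_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """LD-structured diploid dosages for one segment.

    Each haplotype is a latent AR(1) Gaussian (lag-one correlation
    ``ld_rho``) thresholded at the per-SNP MAF quantile; the dosage is the
    sum of the individual's two independent haplotypes.
    """
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (m,))
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must be in (0, 0.5]")
    e = rng.standard_normal((2 * n, m))
    latent = np.empty_like(e)
    latent[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, m):
        latent[:, j] = ld_rho * latent[:, j - 1] + c * e[:, j]
    cuts = stats.norm.ppf(mafs)
    haps = (latent < cuts).astype(np.float64)
    return haps[:n] + haps[n:]


def simulate_weights(
    m: int,
    L: int = 3,
    sparsity: float = 1.0,
    cross_ct_rho: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """L openness-weight vectors sharing a sparse support.

    Nonzero effects are drawn from an L-variate normal with unit variances
    and pairwise correlation ``cross_ct_rho`` across cell types.
    Returns an (L, m) array.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must be in (0, 1]")
    if not 0.0 <= cross_ct_rho <= 1.0:
        raise ValueError("cross_ct_rho must be in [0, 1]")
    k = max(1, int(round(sparsity * m)))
    support = np.sort(rng.choice(m, size=k, replace=False))
    corr = np.full((L, L), cross_ct_rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(L))
    effects = chol @ rng.standard_normal((L, k))
    W = np.zeros((L, m))
    W[:, support] = effects
    return W


def simulate_phenotype(
    X: np.ndarray,
    W: np.ndarray,
    lambdas: tuple[float, ...],
    h2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Quantitative phenotype from the openness scores.

    y = sum_l lambda_l O_l + eps with O_l = X W_l; the noise SD is chosen
    so the segment's genetic component explains exactly ``h2`` of the
    in-sample phenotypic variance.  The null (all lambdas 0) returns
    y ~ N(0, 1).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.all(lambdas == 0.0):
        return rng.standard_normal(X.shape[0]), 1.0
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1) for a causal scenario")
    g = X @ (lambdas @ W)
    var_g = float(np.var(g, ddof=1))
    if var_g == 0.0:
        raise ValueError("degenerate genetic component: Var(g) = 0 with h2 > 0")
    noise_sd = float(np.sqrt(var_g * (1.0 - h2) / h2))
    y = g + noise_sd * rng.standard_normal(X.shape[0])
    return y, noise_sd


def simulate_segment(
    scenario: SimScenario,
    gen: GeneratorConfig,
    rng: np.random.Generator,
) -> SimSegmentData:
    """Draw one segment's genotypes, weights, scores, and phenotype."""
    m = int(rng.integers(gen.m_range[0], gen.m_range[1] + 1))
    mafs = rng.uniform(*gen.maf_range, size=m)
    X = simulate_genotype_block(scenario.n, m, mafs, gen.ld_rho, rng)
    W = simulate_weights(m, gen.n_cell_types, gen.sparsity, gen.cross_ct_rho, rng)
    y, noise_sd = simulate_phenotype(X, W, scenario.lambdas, scenario.h2, rng)
    return SimSegmentData(X=X, W=W, O=X @ W.T, y=y, noise_sd=noise_sd)


def marginal_gwas(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-SNP z-scores from simple linear regression of y on each dosage
    column (slope / SE).  Constant columns give NaN with a warning."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if n <= 2:
        raise ValueError("need n > 2")
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    syy = float(yc @ yc)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        b = sxy / sxx
        rss = syy - b * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
        z = b / se
    bad = sxx == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} constant dosage column(s); z set to NaN")
        z[bad] = np.nan
    return z


#: method labels reported by run_scenario
METHODS = ["owas_ct1", "owas_ct2", "owas_ct3", "union_bonferroni", "owas_joint"]


def run_scenario(
    scenario: SimScenario,
    gen: GeneratorConfig | None = None,
    eta: AcatWeights | None = None,
    collect_pvalues: bool = False,
) -> PowerReport:
    """Run one scenario end to end and report per-method rejection rates.

    Per replicate and segment: simulate the cohort, run the marginal GWAS,
    compute the three single-cell-type segment tests (the cohort itself as
    LD panel, pruning + analytic shrinkage as configured), Cauchy-combine
    them, and reject at the Bonferroni threshold alpha / n_segments.  The
    union method rejects when any single-cell-type p beats threshold / L.
    Under the null scenario the rates are empirical type-I errors.
    """
    if gen is None:
        gen = GeneratorConfig()
    L = gen.n_cell_types
    if eta is None:
        eta = AcatWeights.uniform(L)
    thr = scenario.threshold
    root = np.random.SeedSequence(scenario.seed)
    rep_seeds = root.spawn(scenario.n_reps)
    per_rep = np.zeros((scenario.n_reps, len(METHODS)))
    all_single: list[list[float]] = []
    all_joint: list[float] = []
    for r in range(scenario.n_reps):
        rng = np.random.default_rng(rep_seeds[r])
        rejections = np.zeros(len(METHODS))
        n_tested = 0
        for _ in range(scenario.n_segments):
            seg = simulate_segment(scenario, gen, rng)
            sd = seg.X.std(axis=0, ddof=1)
            if np.any(sd == 0.0):
                continue  # monomorphic draw; essentially impossible at cohort n
            z = marginal_gwas(seg.y, seg.X)
            ld = segment_ld(
                seg.X,
                priority=np.abs(z),  # same ordering as GWAS -log10 p
                r2_threshold=gen.r2_threshold,
                prune=gen.prune,
                shrink=gen.shrink,
            )
            kept = ld.kept_snp_indices
            ps: list[float | None] = []
            for l in range(L):
                st = segment_stat(z[kept], seg.W[l, kept], sd[kept], ld)
                ps.append(st.p)
            _, p_joint = acat(ps, eta)
            n_tested += 1
            for l in range(min(L, 3)):
                if ps[l] is not None and ps[l] < thr:
                    rejections[l] += 1
            if any(pl is not None and pl < thr / L for pl in ps):
                rejections[3] += 1
            if p_joint is not None and p_joint < thr:
                rejections[4] += 1
            if collect_pvalues:
                all_single.append([pl if pl is not None else np.nan for pl in ps])
                all_joint.append(p_joint if p_joint is not None else np.nan)
        per_rep[r] = rejections / max(n_tested, 1)
    return PowerReport(
        methods=list(METHODS),
        rates=per_rep.mean(axis=0),
        rates_sd=per_rep.std(axis=0, ddof=1) if scenario.n_reps > 1 else np.zeros(len(METHODS)),
        per_replicate=per_rep,
        scenario=scenario,
        threshold=thr,
        p_single=np.array(all_single) if collect_pvalues else None,
        p_joint=np.array(all_joint) if collect_pvalues else None,
    )


def power_gain_over_union(
    h2: float,
    n: int = 15_757,
    n_segments: int = 500,
    n_reps: int = 10,
    seed: int = 0,
    gen: GeneratorConfig | None = None,
) -> dict[int, tuple[float, float]]:
    """Per causal-architecture setting, (power_joint, power_union) at the
    given heritability.  Seeds are derived per setting from ``seed``."""
    out = {}
    for setting, lambdas in SETTING_LAMBDAS.items():
        sc = SimScenario(
            lambdas=lambdas, h2=h2, n=n, n_segments=n_segments,
            n_reps=n_reps, seed=seed + setting,
        )
        rep = run_scenario(sc, gen=gen)
        out[setting] = (rep.rate("owas_joint"), rep.rate("union_bonferroni"))
        logger.info(
            "setting %d h2=%g: joint=%.4f union=%.4f", setting, h2, *out[setting]
        )
    return out
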