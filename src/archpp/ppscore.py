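"""Plasticity potential of domain sets: median statistic, randomisation
null, PP-score, empirical p-values and FDR.

The plasticity potential of a domain set ``ds`` in genome ``g`` is the
median of the per-domain distinct-architecture counts::

    PP_ds(g) = MED(N_d : d in ds)

Its null distribution is obtained by drawing ``B`` random domain sets of
the same size, uniformly without replacement, from the genome's annotatable
repertoire, and recomputing the median for each.  With null mean ``mu`` and
sample standard deviation ``sigma`` (B−1 denominator),

    PP-score = (PP_ds(g) − mu) / sigma

and the empirical p-value is the fraction of null replicates at least as
extreme as the observed median, in the direction of the score's sign.
P-values across the terms of a genome are adjusted by Benjamini–Hochberg
step-up FDR.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotatableUniverse, Term, annotatable_universe, resolve_domain_set
from .genome_model import ArchCountMatrix

# status labels for PPResult rows
SCORED = "scored"
NOT_SCOREABLE = "not-scoreable"
DEGENERATE_NULL = "degenerate-null"


class ConfigError(ValueError):
    pass


class InfeasibleNullError(ValueError):
    """Requested set size exceeds the annotatable universe."""


class EnumerationCapError(ValueError):
    """Exact-null enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class ScoreConfig:
    """Null-sampling and correction settings.

    B
        Number of randomisation replicates; the method calls for 2000 or
        higher.
    p_correction
        ``"add-one"`` (default) reports (1 + count)/(1 + B), keeping
        p in (0, 1] at finite B; ``"raw"`` reports the literal count/B.
    fdr_family
        ``"per-genome"`` adjusts across the scored terms of one genome;
        ``"global"`` pools (term, genome) pairs when scoring many nodes.
    share_null_per_k
        Reuse one null stream per (genome, k) across equal-size terms
        instead of a stream per (term, genome).
    """

    B: int = 2000
    seed: int = 0
    p_correction: str = "add-one"
    fdr_family: str = "per-genome"
    share_null_per_k: bool = False

    def __post_init__(self):
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")
        if self.p_correction not in ("add-one", "raw"):
            raise ConfigError(f"unknown p_correction {self.p_correction!r}")
        if self.fdr_family not in ("per-genome", "global"):
            raise ConfigError(f"unknown fdr_family {self.fdr_family!r}")


@dataclass(frozen=True)
class NullSummary:
    mu: float
    sigma: float
    samples: np.ndarray  # the B replicate medians PP_ds^b(g)
    k: int

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class ExactNull:
    """Exhaustive-enumeration null over all C(|u|, k) subsets."""

    mu: float
    sigma: float  # population SD
    medians: np.ndarray  # median of every subset, one per combination
    k: int

    def upper_tail(self, pp: float) -> float:
        return float(np.mean(self.medians >= pp))

    def lower_tail(self, pp: float) -> float:
        return float(np.mean(self.medians <= pp))


def _stable_hash(*parts: str) -> int:
    h = hashlib.sha256("\x1f".join(parts).encode()).digest()
    return int.from_bytes(h[:4], "big")


def _stream(seed: int, genome_id: str, label: str) -> np.random.Generator:
    """Per-(seed, genome, term) RNG stream, independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _stable_hash(genome_id), _stable_hash(label)])
    )


def pp_median(
    effective_set, genome_id: str, matrix: ArchCountMatrix
) -> float | None:
    """Eq.-style median plasticity potential of a domain set.

    Even cardinality takes the midpoint of the two central counts.  Returns
    None for an empty set (not-scoreable).
    """
    domains = sorted(effective_set)
    if not domains:
        return None
    counts = (
        matrix.counts_for(genome_id).reindex(domains).to_numpy(dtype=float)
    )
    if np.any(~np.isfinite(counts)) or np.any(counts <= 0):
        raise ValueError(
            f"domain set contains members absent from genome {genome_id!r}; "
            "resolve against the annotatable universe first"
        )
    return float(np.median(counts))


def _null_medians(
    counts: np.ndarray, k: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of B size-k subsets drawn without replacement (vectorised)."""
    n = counts.shape[0]
    if k == n:
        return np.full(B, float(np.median(counts)))
    # rank a uniform matrix: the k smallest per row form a uniform k-subset
    keys = rng.random((B, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return np.median(counts[idx], axis=1)


def sample_null(
    k: int,
    universe: AnnotatableUniverse,
    matrix: ArchCountMatrix,
    cfg: ScoreConfig,
    rng: np.random.Generator,
) -> NullSummary:
    """Monte-Carlo null for the median PP of a size-k domain set.

    Draws ``cfg.B`` subsets of size k uniformly without replacement from
    the annotatable universe; the per-replicate medians give the null mean
    (sample mean) and SD (B−1 denominator).
    """
    if k < 1:
        raise ValueError("k must be >= 1 (empty set is not-scoreable upstream)")
    if k > len(universe):
        raise InfeasibleNullError(
            f"k={k} exceeds annotatable universe size {len(universe)}"
        )
    domains = sorted(universe.domains)
    counts = matrix.counts_for(universe.genome_id).loc[domains].to_numpy(dtype=float)
    meds = _null_medians(counts, k, cfg.B, rng)
    mu = float(np.mean(meds))
    sigma = float(np.std(meds, ddof=1)) if cfg.B > 1 else 0.0
    return NullSummary(mu=mu, sigma=sigma, samples=meds, k=k)


def exact_null(
    k: int,
    universe: AnnotatableUniverse,
    matrix: ArchCountMatrix,
    cap: int = 10**6,
) -> ExactNull:
    """Enumerate every size-k subset of the universe (test oracle).

    Returns population mean/SD of the subset medians and exact tail masses.
    Refuses when C(|u|, k) exceeds ``cap``.
    """
    n = len(universe)
    if not 1 <= k <= n:
        raise InfeasibleNullError(f"k={k} infeasible for universe of {n}")
    n_comb = math.comb(n, k)
    if n_comb > cap:
        raise EnumerationCapError(
            f"C({n},{k}) = {n_comb} exceeds enumeration cap {cap}"
        )
    domains = sorted(universe.domains)
    counts = matrix.counts_for(universe.genome_id).loc[domains].to_numpy(dtype=float)
    meds = np.array(
        [np.median(c) for c in itertools.combinations(counts, k)], dtype=float
    )
    return ExactNull(
        mu=float(np.mean(meds)),
        sigma=float(np.std(meds)),  # population, ddof=0
        medians=meds,
        k=k,
    )


def pp_score(pp: float, null: NullSummary | ExactNull) -> float:
    """Standardised plasticity potential, (pp − mu)/sigma.

    A degenerate null (sigma = 0) leaves the score undefined; callers map
    that to DEGENERATE_NULL status rather than ±inf.
    """
    if null.sigma == 0.0:
        raise ZeroDivisionError("null SD is zero (degenerate null)")
    return (pp - null.mu) / null.sigma


def empirical_pvalue(
    pp: float, null: NullSummary, correction: str = "add-one"
) -> float:
    """Directional empirical p-value from the stored null replicates.

    Positive score → fraction of replicates with median ≥ pp (inclusive);
    negative score → fraction ≤ pp; zero score → 1 (maximally
    conservative).  The add-one correction (1 + count)/(1 + B) keeps the
    value in (0, 1]; ``correction="raw"`` gives the literal count/B, which
    can be 0 at resolution 1/B.
    """
    samples = null.samples
    B = samples.shape[0]
    if pp > null.mu:
        count = int(np.sum(samples >= pp))
    elif pp < null.mu:
        count = int(np.sum(samples <= pp))
    else:
        return 1.0
    if correction == "add-one":
        return (1 + count) / (1 + B)
    return count / B


def null_upper_tail_pit(
    pp: float, samples: np.ndarray, rng: np.random.Generator
) -> float:
    """Randomised (fuzzy) upper-tail probability integral transform.

    ``(G + V·(E + 1)) / (B + 1)`` with G = #replicates strictly above pp,
    E = #replicates tied with pp, V ~ U(0,1).  When the observed set is
    itself drawn from the null, this is exactly Uniform(0, 1) even for a
    heavily tied discrete statistic — the calibration diagnostic the plain
    directional p-value (which inherits the ties) cannot provide.
    """
    g = int(np.sum(samples > pp))
    e = int(np.sum(samples == pp))
    return (g + rng.random() * (e + 1)) / (samples.shape[0] + 1)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


RESULT_COLUMNS = (
    "term_id", "term_name", "genome_id", "k", "pp",
    "null_mu", "null_sigma", "pp_score", "p_value", "fdr", "status",
)


def score_terms(
    terms,
    genome_id: str,
    matrix: ArchCountMatrix,
    cfg: ScoreConfig = ScoreConfig(),
    universe: AnnotatableUniverse | None = None,
) -> pd.DataFrame:
    """Score every term against one genome; one row per term.

    The annotatable universe defaults to the pooled members of ``terms``
    intersected with the genome's repertoire.  Terms whose effective set is
    empty are returned with status not-scoreable; a term covering the whole
    universe has a single possible subset, hence a degenerate null.  RNG
    streams derive from (seed, genome, term) so results do not depend on
    term order; with ``share_null_per_k`` they derive from (seed, genome, k).
    FDR is adjusted across this genome's scored terms (the global family is
    assembled by the caller via :func:`attach_fdr`).
    """
    terms = list(terms)
    if universe is None:
        universe = annotatable_universe(genome_id, matrix, terms)
    rows = []
    null_cache: dict[int, NullSummary] = {}
    for t in terms:
        eff, k = resolve_domain_set(t, universe)
        row = {
            "term_id": t.term_id, "term_name": t.name, "genome_id": genome_id,
            "k": k, "pp": np.nan, "null_mu": np.nan, "null_sigma": np.nan,
            "pp_score": np.nan, "p_value": np.nan, "fdr": np.nan,
        }
        if k == 0:
            row["status"] = NOT_SCOREABLE
            rows.append(row)
            continue
        pp = pp_median(eff, genome_id, matrix)
        if cfg.share_null_per_k:
            null = null_cache.get(k)
            if null is None:
                rng = _stream(cfg.seed, genome_id, f"k={k}")
                null = null_cache[k] = sample_null(k, universe, matrix, cfg, rng)
        else:
            rng = _stream(cfg.seed, genome_id, t.term_id)
            null = sample_null(k, universe, matrix, cfg, rng)
        row["pp"], row["null_mu"], row["null_sigma"] = pp, null.mu, null.sigma
        if null.degenerate:
            row["status"] = DEGENERATE_NULL
            rows.append(row)
            continue
        row["pp_score"] = pp_score(pp, null)
        row["p_value"] = empirical_pvalue(pp, null, cfg.p_correction)
        row["status"] = SCORED
        rows.append(row)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if cfg.fdr_family == "per-genome":
        out = attach_fdr(out)
    return out


def attach_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """Fill the fdr column by BH adjustment over the scored rows."""
    out = results.copy()
    mask = out["status"] == SCORED
    if mask.any():
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out


def results_to_tsv(results: pd.DataFrame, path_or_buf=None):
    """Write the scoring table with floats at 6 significant digits."""
    return results.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6g")
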