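"""Pairwise molecular-evolution rates and the neutrality likelihood-ratio test.

For each orthologous coding-sequence pair this module estimates Ka
(nonsynonymous substitutions per nonsynonymous site), Ks (synonymous
substitutions per synonymous site) and their ratio omega two ways:

* a Nei–Gojobori (1986) counting estimate with Jukes–Cantor correction,
  kept as an independent cross-check;
* a maximum-likelihood fit of a GY94-style codon model, run twice — omega
  free and omega fixed at 1 — so that LR = 2(lnL_free − lnL_fixed) gives a
  nested likelihood-ratio statistic.  A pair is called neutrally evolving
  when LR falls below the chi-square(1) 90th percentile (2.71, i.e. 5%
  one-sided at the omega = 1 boundary).

Rank-level summaries (Spearman age trends, Mann–Whitney lineage contrasts)
mirror the comparative statistics applied to age-ranked orthologous pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from ._codon import (
    AMINO_ACID,
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonModel,
    codon_frequencies_f3x4,
    encode_codons,
    flux_fractions,
)

NEUTRALITY_LR_CUTOFF = 2.71  # chi2(1) 90th percentile; 5% one-sided at the boundary

_T_BOUNDS = (1e-6, 50.0)
_KAPPA_BOUNDS = (1e-3, 100.0)
_OMEGA_BOUNDS = (1e-4, 20.0)
_GRID_T = (0.05, 0.5, 2.0)
_GRID_KAPPA = (0.5, 2.0, 8.0)
_GRID_OMEGA = (0.1, 1.0, 4.0)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class CodonAlignment:
    """A gapless pairwise codon alignment (standard genetic code)."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 or not a:
            raise ValueError("alignment length must be a positive multiple of 3")
        for seq in (a, b):
            for k in range(0, len(seq), 3):
                if seq[k : k + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon at codon {k // 3}")

    @property
    def length(self) -> int:
        """Number of codons."""
        return len(self.seq_a) // 3

    def codon_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return encode_codons(self.seq_a), encode_codons(self.seq_b)


@dataclass(frozen=True)
class CodonModelFit:
    t: float
    kappa: float
    omega: float
    lnl: float
    converged: bool


@dataclass
class SelectionResult:
    pair_id: str
    ka: float
    ks: float
    omega_ml: float
    lnl_fixed: float
    lnl_free: float
    lr: float
    neutral: bool
    age_rank: str | None = None
    converged: bool = True
    ks_saturated: bool = False


@dataclass(frozen=True)
class NG86Result:
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    ps: float
    pn: float
    ka: float
    ks: float

    @property
    def ka_defined(self) -> bool:
        return math.isfinite(self.ka)

    @property
    def ks_defined(self) -> bool:
        return math.isfinite(self.ks)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986 counting


@lru_cache(maxsize=1)
def _ng86_site_fractions() -> np.ndarray:
    """Per-codon synonymous site count: sum over positions of the fraction of
    one-step changes that are synonymous, mutations to stops excluded from
    numerator and denominator."""
    out = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        total = 0.0
        for pos in range(3):
            syn = valid = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                valid += 1
                if AMINO_ACID[CODON_INDEX[mutant]] == AMINO_ACID[i]:
                    syn += 1
            if valid:
                total += syn / valid
        out[i] = total
    return out


@lru_cache(maxsize=4096)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences for one codon pair, averaged
    over all minimal mutational pathways; pathways through stop codons are
    discarded unless every pathway is blocked."""
    positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not positions:
        return 0.0, 0.0

    def aa(codon: str) -> str:
        return "*" if codon in STOP_CODONS else AMINO_ACID[CODON_INDEX[codon]]

    all_paths: list[tuple[float, float]] = []
    open_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        current = codon_a
        syn = non = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if aa(current) == aa(nxt):
                syn += 1.0
            else:
                non += 1.0
            current = nxt
        all_paths.append((syn, non))
        if not blocked:
            open_paths.append((syn, non))
    use = open_paths or all_paths
    s = sum(p[0] for p in use) / len(use)
    n = sum(p[1] for p in use) / len(use)
    return s, n


def _jukes_cantor(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def ng86_counts(aln: CodonAlignment) -> NG86Result:
    """Nei–Gojobori (1986) site/difference counts with Jukes–Cantor correction.

    Synonymous site fractions come from one-step neighbor enumeration under
    the standard code; multi-position codon differences are averaged over all
    minimal mutational pathways.  Ka/Ks are NaN (flagged undefined) when the
    Jukes–Cantor argument is non-positive (saturation).
    """
    idx_a, idx_b = aln.codon_indices()
    site = _ng86_site_fractions()
    s_sites = 0.5 * (site[idx_a].sum() + site[idx_b].sum())
    n_sites = 3.0 * aln.length - s_sites
    s_diffs = n_diffs = 0.0
    for ia, ib in zip(idx_a, idx_b):
        if ia == ib:
            continue
        s, n = _pathway_diffs(SENSE_CODONS[ia], SENSE_CODONS[ib])
        s_diffs += s
        n_diffs += n
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    return NG86Result(
        s_sites=float(s_sites),
        n_sites=float(n_sites),
        s_diffs=float(s_diffs),
        n_diffs=float(n_diffs),
        ps=float(ps),
        pn=float(pn),
        ka=_jukes_cantor(pn),
        ks=_jukes_cantor(ps),
    )


# ---------------------------------------------------------------------------
# GY94 likelihood and pairwise fit


def _pair_counts(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compressed site patterns: (i indices, j indices, weights)."""
    idx_a, idx_b = aln.codon_indices()
    flat = idx_a * N_CODONS + idx_b
    uniq, counts = np.unique(flat, return_counts=True)
    return uniq // N_CODONS, uniq % N_CODONS, counts.astype(float)


def _loglik_from_counts(ii, jj, ww, model: CodonModel, t: float) -> float:
    P = model.transition_probs(t)
    vals = model.pi[ii] * P[ii, jj]
    if np.any(vals <= 0):
        vals = np.maximum(vals, 1e-300)
    return float(ww @ np.log(vals))


def gy94_loglik(
    aln: CodonAlignment,
    t: float,
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray | None = None,
) -> float:
    """Log-likelihood of a pairwise codon alignment under the GY94 model.

    lnL = sum over codon columns of log(pi_i * P(t)_{ij}); by reversibility
    the value is invariant to swapping the two sequences.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    ii, jj, ww = _pair_counts(aln)
    model = CodonModel.build(kappa, omega, codon_freqs)
    lnl = _loglik_from_counts(ii, jj, ww, model, t)
    if not math.isfinite(lnl):
        raise FloatingPointError(
            f"non-finite log-likelihood at t={t}, kappa={kappa}, omega={omega}"
        )
    return lnl


def fit_pair(
    aln: CodonAlignment,
    fix_omega: float | None = None,
    codon_freq_mode: Literal["uniform", "f3x4"] = "uniform",
    n_refine: int = 2,
) -> CodonModelFit:
    """Maximum-likelihood fit of (t, kappa[, omega]) for one pair.

    Deterministic multi-start: the likelihood is evaluated on a fixed
    3x3(x3) grid over t, kappa and (unless fixed) omega, and the best
    ``n_refine`` starts are polished with bounded L-BFGS-B in log-parameter
    space.
    """
    freqs = None if codon_freq_mode == "uniform" else codon_frequencies_f3x4([aln.seq_a, aln.seq_b])
    ii, jj, ww = _pair_counts(aln)
    free_omega = fix_omega is None

    def unpack(x: np.ndarray) -> tuple[float, float, float]:
        t, kappa = math.exp(x[0]), math.exp(x[1])
        omega = math.exp(x[2]) if free_omega else float(fix_omega)
        return t, kappa, omega

    def negloglik(x: np.ndarray) -> float:
        t, kappa, omega = unpack(x)
        model = CodonModel.build(kappa, omega, freqs)
        lnl = _loglik_from_counts(ii, jj, ww, model, t)
        return -lnl if math.isfinite(lnl) else 1e12

    starts = []
    omega_grid = _GRID_OMEGA if free_omega else (float(fix_omega),)
    for t0 in _GRID_T:
        for k0 in _GRID_KAPPA:
            for w0 in omega_grid:
                x0 = [math.log(t0), math.log(k0)] + ([math.log(w0)] if free_omega else [])
                starts.append(np.array(x0))
    scored = sorted(starts, key=lambda x: negloglik(x))

    bounds = [tuple(map(math.log, _T_BOUNDS)), tuple(map(math.log, _KAPPA_BOUNDS))]
    if free_omega:
        bounds.append(tuple(map(math.log, _OMEGA_BOUNDS)))

    best: optimize.OptimizeResult | None = None
    for x0 in scored[: max(1, n_refine)]:
        try:
            res = optimize.minimize(
                negloglik, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except FloatingPointError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    t, kappa, omega = unpack(best.x)
    return CodonModelFit(t=t, kappa=kappa, omega=omega, lnl=-float(best.fun), converged=bool(best.success))


def ml_ka_ks(
    fit: CodonModelFit,
    aln: CodonAlignment,
    codon_freq_mode: Literal["uniform", "f3x4"] = "uniform",
) -> tuple[float, float]:
    """Ka and Ks from a fitted codon model.

    The scaled rate matrix splits the substitution flux into synonymous and
    nonsynonymous fractions rho_S(omega), rho_N(omega); site proportions are
    the same fractions at omega = 1 (mutational opportunity).  Then
    Ks = t·rho_S(omega)/(3·rho_S1) and Ka = t·rho_N(omega)/(3·rho_N1), so
    Ka/Ks equals the fitted omega.
    """
    freqs = None if codon_freq_mode == "uniform" else codon_frequencies_f3x4([aln.seq_a, aln.seq_b])
    rho_s, rho_n = flux_fractions(fit.kappa, fit.omega, freqs)
    rho_s1, rho_n1 = flux_fractions(fit.kappa, 1.0, freqs)
    if rho_s1 <= 0:
        raise ZeroDivisionError("no synonymous mutational opportunity")
    ks = fit.t * rho_s / (3.0 * rho_s1)
    ka = fit.t * rho_n / (3.0 * rho_n1)
    return ka, ks


def neutrality_test(
    aln: CodonAlignment,
    lr_cutoff: float = NEUTRALITY_LR_CUTOFF,
    pair_id: str = "",
    age_rank: str | None = None,
    codon_freq_mode: Literal["uniform", "f3x4"] = "uniform",
) -> SelectionResult:
    """Likelihood-ratio neutrality classification of one orthologous pair.

    Two fits are run, omega free and omega fixed at 1; LR = 2(lnL_free −
    lnL_fixed), clamped to 0 when the optimizer leaves it marginally
    negative.  The pair is called neutral when LR < ``lr_cutoff`` (default
    2.71, the 5% point of the chi-square(1) boundary test).
    """
    free = fit_pair(aln, codon_freq_mode=codon_freq_mode)
    fixed = fit_pair(aln, fix_omega=1.0, codon_freq_mode=codon_freq_mode)
    lr = 2.0 * (free.lnl - fixed.lnl)
    if lr < 0:
        if lr < -1e-2:
            # free fit trapped below the nested fixed fit: retry from the fixed optimum
            retry = _refit_from(aln, fixed, codon_freq_mode)
            if retry.lnl > free.lnl:
                free = retry
                lr = 2.0 * (free.lnl - fixed.lnl)
        lr = max(lr, 0.0)
    ka, ks = ml_ka_ks(free, aln, codon_freq_mode)
    ng = ng86_counts(aln)
    return SelectionResult(
        pair_id=pair_id,
        ka=ka,
        ks=ks,
        omega_ml=free.omega,
        lnl_fixed=fixed.lnl,
        lnl_free=free.lnl,
        lr=lr,
        neutral=lr < lr_cutoff,
        age_rank=age_rank,
        converged=free.converged and fixed.converged,
        ks_saturated=not ng.ks_defined,
    )


def _refit_from(aln, fixed: CodonModelFit, codon_freq_mode) -> CodonModelFit:
    freqs = None if codon_freq_mode == "uniform" else codon_frequencies_f3x4([aln.seq_a, aln.seq_b])
    ii, jj, ww = _pair_counts(aln)

    def negloglik(x):
        model = CodonModel.build(math.exp(x[1]), math.exp(x[2]), freqs)
        return -_loglik_from_counts(ii, jj, ww, model, math.exp(x[0]))

    x0 = np.log([max(fixed.t, 1e-6), fixed.kappa, 1.0])
    bounds = [tuple(map(math.log, b)) for b in (_T_BOUNDS, _KAPPA_BOUNDS, _OMEGA_BOUNDS)]
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 200, "ftol": 1e-10})
    t, kappa, omega = math.exp(res.x[0]), math.exp(res.x[1]), math.exp(res.x[2])
    return CodonModelFit(t=t, kappa=kappa, omega=omega, lnl=-float(res.fun), converged=bool(res.success))


# ---------------------------------------------------------------------------
# alignment utility


def backthread_codons(protein_aln_a: str, protein_aln_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread CDS codons through a pairwise protein alignment, dropping
    gapped columns, to obtain a gapless codon alignment."""
    if len(protein_aln_a) != len(protein_aln_b):
        raise ValueError("protein alignment rows differ in length")
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(protein_aln_a, protein_aln_b):
        if ca != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        if ca != "-" and cb != "-":
            out_a.append(codon_a)
            out_b.append(codon_b)
    return CodonAlignment("".join(out_a), "".join(out_b))


# ---------------------------------------------------------------------------
# rank-level statistics

_DEFAULT_RANK_ORDER = ("0", "6", "7", "8", "9", "10", "A")


def _exact_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    sx, sy = xr.std(), yr.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho = float(np.corrcoef(xr, yr)[0, 1])
    n = len(x)
    perms = np.array(list(itertools.permutations(yr)))
    xc = xr - xr.mean()
    rhos = (perms - yr.mean()) @ xc / (n * sx * sy)
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p


def spearman_trend(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties: exact permutation p-value
    for n <= 9, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    if len(x) <= 9:
        return _exact_spearman(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank_position(rank: str, order: Sequence[str]) -> int | None:
    try:
        return order.index(rank)  # type: ignore[union-attr]
    except ValueError:
        return None


def age_trend(
    results: Iterable[SelectionResult],
    value: Literal["Ka", "Ks", "omega", "neutral_fraction"],
    rank_order: Sequence[str] = _DEFAULT_RANK_ORDER,
    include_ancient: bool = False,
) -> tuple[float, float]:
    """Spearman correlation of a selection statistic with orthogroup age rank.

    Non-ranked pairs are ignored; the ancient rank ("A") is excluded by
    default.  ``neutral_fraction`` correlates the per-rank fraction of
    neutral calls with rank; the per-pair statistics correlate each pair's
    value with its rank position.
    """
    order = list(rank_order)
    if not include_ancient and "A" in order:
        order.remove("A")
    kept: list[tuple[int, SelectionResult]] = []
    for r in results:
        if r.age_rank is None or not r.converged:
            continue
        pos = _rank_position(str(r.age_rank), order)
        if pos is not None:
            kept.append((pos, r))
    if value == "neutral_fraction":
        by_rank: dict[int, list[bool]] = {}
        for pos, r in kept:
            by_rank.setdefault(pos, []).append(r.neutral)
        if len(by_rank) < 3:
            raise ValueError("need at least 3 distinct age ranks")
        xs = sorted(by_rank)
        ys = [float(np.mean(by_rank[p])) for p in xs]
        return spearman_trend(xs, ys)
    attr = {"Ka": "ka", "Ks": "ks", "omega": "omega_ml"}[value]
    xs = [pos for pos, _ in kept]
    ys = [getattr(r, attr) for _, r in kept]
    pairs = [(x, y) for x, y in zip(xs, ys) if math.isfinite(y)]
    if len({x for x, _ in pairs}) < 3:
        raise ValueError("need at least 3 distinct age ranks")
    return spearman_trend([p[0] for p in pairs], [p[1] for p in pairs])


def lineage_compare(
    results_a: Iterable[SelectionResult],
    results_b: Iterable[SelectionResult],
    value: Literal["Ka", "Ks", "omega"],
) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney rank-sum comparison of a statistic between two
    lineages; returns (U, p, direction) where direction names the sample
    with the larger median."""
    attr = {"Ka": "ka", "Ks": "ks", "omega": "omega_ml"}[value]
    xs = [getattr(r, attr) for r in results_a if math.isfinite(getattr(r, attr))]
    ys = [getattr(r, attr) for r in results_b if math.isfinite(getattr(r, attr))]
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    u, p = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="auto")
    direction = "a" if np.median(xs) > np.median(ys) else "b"
    return float(u), float(p), direction
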