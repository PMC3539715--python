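"""Mirrortree co-evolution tests on paired branch-wise ω vectors.

For each interacting pair the branch-specific selective constraints
(ω = Ka/Ks) of the two genes are aligned on their shared branches (a
"mirrortree"); the Spearman correlation ρ between the two vectors
measures co-evolution of constraint.  The mean ρ over true pairs is
compared to the distribution of means from pseudo-pair datasets of the
same size, which inherit all the branch-level structure of the data
(branch effects, branch lengths) without interaction.  Because ω is
heavily right-skewed with occasional extreme branches, rank correlation
is the primary statistic and very large values (ω ≥ 5 by default) can
be dropped; Pearson r is available to demonstrate its outlier
sensitivity.

The shared-selection test asks a complementary directional question:
on a given branch, do both members of a pair exceed an ω threshold
(> 1 directional selection, > 0.5 relaxed constraint) more often than
the product of the marginal exceedance frequencies predicts (1-df χ²
on the concordant count)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import (
    BranchOmegaTable,
    InteractionNetwork,
    MirrorTree,
    Pair,
    PermutationResult,
    canonical_pair,
)
from .null_models import sample_pseudo_pairs
from .phylogeny import BRANCHES

log = logging.getLogger(__name__)

DEFAULT_OMEGA_CUTOFF = 5.0
DEFAULT_MIN_BRANCHES = 6

#: Clade-removal map: removing a species removes its terminal branch;
#: removing a clade removes its tip branches and internal stems.  The
#: horse/dog/cow clade's stem is the central branch ("root").
DEFAULT_CLADES: dict[str, frozenset[str]] = {
    "Human": frozenset({"human"}),
    "Chimpanzee": frozenset({"chimpanzee"}),
    "Macaque": frozenset({"macaque"}),
    "Mouse": frozenset({"mouse"}),
    "Rat": frozenset({"rat"}),
    "Horse": frozenset({"horse"}),
    "Dog": frozenset({"dog"}),
    "Cow": frozenset({"cow"}),
    "Human/Chimp": frozenset({"human", "chimpanzee", "human-chimp"}),
    "Primates": frozenset(
        {"human", "chimpanzee", "macaque", "human-chimp", "primates"}
    ),
    "Rodents": frozenset({"mouse", "rat", "mouse-rat"}),
    "Horse/Dog": frozenset({"horse", "dog", "horse-dog"}),
    "Horse/Dog/Cow": frozenset({"horse", "dog", "cow", "horse-dog", "root"}),
}


def build_mirrortree(pair: Pair, table: BranchOmegaTable) -> MirrorTree:
    """Paired ω vectors over the intersection of the two genes' branch
    sets, in canonical branch order."""
    a, b = canonical_pair(*pair)
    shared = table.branches(a) & table.branches(b)
    branches = tuple(br for br in BRANCHES if br in shared)
    return MirrorTree(
        pair=(a, b),
        branches=branches,
        omega_a=np.array([table.omega(a, br) for br in branches]),
        omega_b=np.array([table.omega(b, br) for br in branches]),
    )


def filter_omega(mirror: MirrorTree, cutoff: float) -> MirrorTree:
    """Drop branches where *either* member's ω ≥ cutoff (large ω values
    carry large sampling variances)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive (or infinite)")
    keep = (mirror.omega_a < cutoff) & (mirror.omega_b < cutoff)
    return MirrorTree(
        pair=mirror.pair,
        branches=tuple(b for b, k in zip(mirror.branches, keep) if k),
        omega_a=mirror.omega_a[keep],
        omega_b=mirror.omega_b[keep],
    )


def _corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape 2-d arrays;
    NaN where either row is constant."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    out = np.full(x.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def pair_correlation(
    mirror: MirrorTree,
    method: str = "spearman",
    min_branches: int = DEFAULT_MIN_BRANCHES,
) -> float | None:
    """Correlation of the paired ω vectors; None (pair excluded) when
    fewer than ``min_branches`` branches remain or a vector is constant.

    Spearman uses average ranks for ties.
    """
    if min_branches < 2:
        raise ValueError("min_branches must be >= 2")
    if mirror.n_branches < min_branches:
        return None
    if method == "spearman":
        x = stats.rankdata(mirror.omega_a)
        y = stats.rankdata(mirror.omega_b)
    elif method == "pearson":
        x = np.asarray(mirror.omega_a, dtype=float)
        y = np.asarray(mirror.omega_b, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = _corr_rows(x[None, :], y[None, :])[0]
    return None if np.isnan(r) else float(r)


# ---------------------------------------------------------------------------
# vectorised batch correlations over a dense gene × branch matrix
# ---------------------------------------------------------------------------


def _batch_rhos(
    m: np.ndarray,
    valid: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    min_branches: int,
    method: str = "spearman",
) -> np.ndarray:
    """ρ for many pairs at once.  ``m`` is the genes × 13 ω matrix (NaN
    missing), ``valid`` the usable-entry mask (finite, below cutoff,
    branch not excluded).  Pairs are grouped by their shared-branch
    mask so ranking vectorises within each group.  NaN marks excluded
    pairs (too few branches or constant ranks)."""
    n = len(ia)
    out = np.full(n, np.nan)
    common = valid[ia] & valid[ib]
    counts = common.sum(axis=1)
    eligible = np.nonzero(counts >= min_branches)[0]
    if eligible.size == 0:
        return out
    keys = [common[i].tobytes() for i in eligible]
    groups: dict[bytes, list[int]] = {}
    for i, k in zip(eligible.tolist(), keys):
        groups.setdefault(k, []).append(i)
    for k, idxs in groups.items():
        mask = np.frombuffer(k, dtype=bool)
        cols = np.nonzero(mask)[0]
        idxs = np.asarray(idxs)
        a = m[ia[idxs]][:, cols]
        b = m[ib[idxs]][:, cols]
        if method == "spearman":
            a = stats.rankdata(a, axis=1)
            b = stats.rankdata(b, axis=1)
        out[idxs] = _corr_rows(a, b)
    return out


@dataclass(frozen=True)
class CoevolutionResult:
    """Observed mean ρ over true pairs vs the distribution of means
    from same-size pseudo-pair datasets."""

    n_pairs: int
    pair_rhos: Mapping[Pair, float]
    mean_rho: float
    perm: PermutationResult
    n_excluded: int
    omega_cutoff: float
    min_branches: int
    excluded_branches: frozenset[str]
    method: str = "spearman"

    @property
    def mean_of_means(self) -> float:
        return self.perm.null_mean

    @property
    def difference(self) -> float:
        return self.mean_rho - self.perm.null_mean


def _valid_mask(
    m: np.ndarray, cutoff: float, excluded_branches: frozenset[str]
) -> np.ndarray:
    valid = np.isfinite(m) & (m < cutoff)
    for br in excluded_branches:
        if br not in BRANCHES:
            raise ValueError(f"unknown branch label {br!r}")
        valid[:, BRANCHES.index(br)] = False
    return valid


def mean_rho_test(
    network: InteractionNetwork,
    table: BranchOmegaTable,
    n_null: int = 1000,
    cutoff: float = DEFAULT_OMEGA_CUTOFF,
    min_branches: int = DEFAULT_MIN_BRANCHES,
    excluded_branches: frozenset[str] = frozenset(),
    seed: int = 0,
    method: str = "spearman",
) -> CoevolutionResult:
    """Permutation test of mean mirrortree correlation.

    Eligible true pairs are network edges whose mirrortrees retain at
    least ``min_branches`` branches after the ω cutoff and branch
    exclusions and whose rank vectors are non-constant.  Each null
    replicate draws a pseudo-pair set of the same size meeting the same
    requirements (degree-weighted genes, no true edges, unique pairs)
    and records its mean ρ; the empirical p is one-sided for the
    observed mean exceeding the null means.
    """
    if frozenset(excluded_branches) >= set(BRANCHES):
        raise ValueError("cannot exclude every branch")
    genes = [g for g in table.genes if g in network]
    if len(genes) < 2:
        raise ValueError("fewer than two network genes carry omega data")
    m, genes = table.matrix(genes)
    valid = _valid_mask(m, cutoff, frozenset(excluded_branches))
    index_of = {g: i for i, g in enumerate(genes)}

    true_pairs = [
        (a, b) for a, b in network.pairs() if a in index_of and b in index_of
    ]
    n_missing = network.n_edges - len(true_pairs)
    if n_missing:
        log.info("mean_rho_test: %d pairs lack omega data and are skipped", n_missing)
    if not true_pairs:
        raise ValueError("no network pair has omega data for both genes")
    ia = np.array([index_of[a] for a, _ in true_pairs])
    ib = np.array([index_of[b] for _, b in true_pairs])
    rhos = _batch_rhos(m, valid, ia, ib, min_branches, method)
    ok = np.isfinite(rhos)
    n_obs = int(ok.sum())
    n_excluded = len(true_pairs) - n_obs
    if n_obs < 1:
        raise ValueError("no eligible pair after filtering")
    observed = float(rhos[ok].mean())
    pair_rhos = {
        p: float(r) for p, r, keep in zip(true_pairs, rhos, ok) if keep
    }

    # eligibility predicate for pseudo-pairs: evaluated on candidate
    # index arrays; constant-rank pairs are filtered after drawing.
    def predicate(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return (valid[lo] & valid[hi]).sum(axis=1) >= min_branches

    null = np.empty(n_null)
    for i in range(n_null):
        rep_seed = seed + i + 1
        pps = sample_pseudo_pairs(
            network,
            n_obs,
            seed=rep_seed,
            candidates=genes,
            predicate=predicate,
        )
        ja = np.array([index_of[a] for a, _ in pps.pairs])
        jb = np.array([index_of[b] for _, b in pps.pairs])
        r = _batch_rhos(m, valid, ja, jb, min_branches, method)
        null[i] = np.nanmean(r)
    perm = PermutationResult.from_null(observed, null, "greater", seed)
    return CoevolutionResult(
        n_pairs=n_obs,
        pair_rhos=pair_rhos,
        mean_rho=observed,
        perm=perm,
        n_excluded=n_excluded,
        omega_cutoff=cutoff,
        min_branches=min_branches,
        excluded_branches=frozenset(excluded_branches),
        method=method,
    )


@dataclass(frozen=True)
class CladeRemovalRow:
    clade: str
    n_ppis: int
    p: float
    p_label: str
    mean_rho: float
    mean_of_means: float
    difference: float


def clade_removal_scan(
    network: InteractionNetwork,
    table: BranchOmegaTable,
    clades: Mapping[str, frozenset[str]] | None = None,
    n_null: int = 1000,
    cutoff: float = DEFAULT_OMEGA_CUTOFF,
    min_branches: int = DEFAULT_MIN_BRANCHES,
    seed: int = 0,
) -> list[CladeRemovalRow]:
    """Sensitivity of the co-evolution signal to removing each clade's
    branches; the first row ("None") is the full-data analysis.  Pair
    eligibility is re-evaluated per removal."""
    if clades is None:
        clades = DEFAULT_CLADES
    for name, branches in clades.items():
        unknown = set(branches) - set(BRANCHES)
        if unknown:
            raise ValueError(f"clade {name!r} names unknown branches {sorted(unknown)}")
    rows = []
    scans: list[tuple[str, frozenset[str]]] = [("None", frozenset())]
    scans += [(name, frozenset(b)) for name, b in clades.items()]
    for name, excluded in scans:
        res = mean_rho_test(
            network,
            table,
            n_null=n_null,
            cutoff=cutoff,
            min_branches=min_branches,
            excluded_branches=excluded,
            seed=seed,
        )
        rows.append(
            CladeRemovalRow(
                clade=name,
                n_ppis=res.n_pairs,
                p=res.perm.p_empirical,
                p_label=res.perm.p_label,
                mean_rho=res.mean_rho,
                mean_of_means=res.mean_of_means,
                difference=res.difference,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# shared directional selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SharedSelectionResult:
    """Observed vs expected count of pairs where both members exceed an
    ω threshold on one branch (1-df χ² on the concordant count)."""

    branch: str
    threshold: float
    n_pairs: int
    observed: int
    expected: float
    f_first: float
    f_second: float
    chi2: float | None
    p: float | None
    valid: bool
    note: str = ""


def shared_selection_test(
    network: InteractionNetwork,
    table: BranchOmegaTable,
    branch: str,
    threshold: float = 1.0,
    min_pairs: int = 20,
) -> SharedSelectionResult:
    """Test for an excess of pairs whose members *both* exceed
    ``threshold`` on ``branch``.

    Expected concordant count is n·f₁·f₂ from the marginal exceedance
    frequencies of first and second pair members (canonical order); the
    χ² is the 1-df goodness-of-fit on the concordant count, one-sided
    for excess.  Branches with too few pairs or too few exceedances for
    a valid χ² are flagged without a p-value.
    """
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    x = []
    y = []
    for a, b in network.pairs():
        if a not in table or b not in table:
            continue
        if branch not in table.branches(a) or branch not in table.branches(b):
            continue
        x.append(table.omega(a, branch) > threshold)
        y.append(table.omega(b, branch) > threshold)
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    n = x.size
    if n == 0:
        return SharedSelectionResult(
            branch, threshold, 0, 0, 0.0, 0.0, 0.0, None, None, False,
            "no pairs with omega on this branch",
        )
    f1 = float(x.mean())
    f2 = float(y.mean())
    observed = int(np.sum(x & y))
    expected = n * f1 * f2
    if n < min_pairs:
        return SharedSelectionResult(
            branch, threshold, n, observed, expected, f1, f2, None, None, False,
            f"fewer than {min_pairs} pairs",
        )
    if expected < 5 or (n - expected) < 5:
        return SharedSelectionResult(
            branch, threshold, n, observed, expected, f1, f2, None, None, False,
            "too few observations for a valid chi-square test",
        )
    chi2 = (observed - expected) ** 2 / expected + (
        (n - observed) - (n - expected)
    ) ** 2 / (n - expected)
    tail = float(stats.chi2.sf(chi2, df=1))
    p = tail / 2.0 if observed >= expected else 1.0 - tail / 2.0
    return SharedSelectionResult(
        branch, threshold, n, observed, expected, f1, f2, float(chi2), p, True
    )
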