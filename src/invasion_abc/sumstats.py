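"""One-, two- and three-population microsatellite summary statistics.

The catalog follows the classic ABC toolbox decomposition, averaged over
loci: per population sample — mean number of alleles (NAL), mean unbiased
gene diversity (HET), mean allele-size variance (VAR), mean Garza–Williamson
M (MGW); per unordered pair — the three pooled-sample analogues (N2P, H2P,
V2P), Weir–Cockerham FST, both directions of an assignment log-likelihood
(LIK), the shared-allele distance (DAS) and the mean squared difference in
allele size ((δμ)², DM2); per unordered triplet — one maximum-likelihood-style
admixture coefficient (AML) for each of the three choices of admixed target.

Catalog size for P populations is therefore 4P + 8·C(P,2) + 3·C(P,3); the
reduced "expert" estimation set is NAL + HET per population, all pairwise
FST values and one AML per declared admixture triplet (2P + C(P,2) + T).

Missing alleles (sentinel 0) are skipped locus-wise; a locus unusable in any
member of a pair or triplet is dropped from that statistic's average.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_data import MISSING, GenotypeDataset

__all__ = [
    "StatVector",
    "one_sample_stats",
    "two_sample_stats",
    "three_sample_stats",
    "full_catalog",
    "estimation_subset",
    "catalog_names",
    "estimation_subset_names",
    "wc_fst",
]

ONE_SAMPLE_STATS = ("NAL", "HET", "VAR", "MGW")
TWO_SAMPLE_STATS = ("N2P", "H2P", "V2P", "FST", "LIKAB", "LIKBA", "DAS", "DM2")


@dataclass
class StatVector:
    """Ordered, named statistic values with population-arity annotations."""

    names: list[str]
    values: np.ndarray
    arity: list[int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("statistic names must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.names) == len(self.values) == len(self.arity)):
            raise ValueError("names, values and arity must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def subset(self, names: list[str]) -> "StatVector":
        idx = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"unknown statistics: {missing}")
        sel = [idx[n] for n in names]
        return StatVector(list(names), self.values[sel], [self.arity[i] for i in sel])


# ---------------------------------------------------------------------------
# Per-locus views
# ---------------------------------------------------------------------------

class _PopLocus:
    """Counts of one population at one locus over that locus's allele set."""

    __slots__ = ("indiv_counts", "allele_counts", "n_copies", "n_ind")

    def __init__(self, geno: np.ndarray, values: np.ndarray):
        # geno: (n, 2) raw allele sizes; values: sorted union alleles at locus
        ok = np.all(geno != MISSING, axis=1)  # an individual with any missing
        g = geno[ok]  # allele is skipped at this locus
        idx = np.searchsorted(values, g)
        n = g.shape[0]
        counts = np.zeros((n, len(values)), dtype=np.int16)
        if n:
            rows = np.repeat(np.arange(n), 2)
            np.add.at(counts, (rows, idx.ravel()), 1)
        self.indiv_counts = counts
        self.allele_counts = counts.sum(axis=0).astype(np.int64)
        self.n_copies = int(2 * n)
        self.n_ind = int(n)

    def het_counts(self) -> np.ndarray:
        """Number of individuals carrying exactly one copy of each allele."""
        return (self.indiv_counts == 1).sum(axis=0).astype(np.int64)


class DatasetView:
    """Pre-indexed per-locus allele counts for every population."""

    def __init__(self, dataset: GenotypeDataset):
        self.dataset = dataset
        self.pops = list(dataset.populations)
        self.locus_values: list[np.ndarray] = []
        self.pop_locus: dict[str, list[_PopLocus]] = {p: [] for p in self.pops}
        for j in range(dataset.n_loci):
            pooled = np.concatenate(
                [dataset.pop_alleles(p, j) for p in self.pops]
            )
            values = np.unique(pooled) if len(pooled) else np.empty(0, dtype=np.int64)
            self.locus_values.append(values)
            for p in self.pops:
                self.pop_locus[p].append(
                    _PopLocus(dataset.genotypes[p][:, j, :], values)
                )


def _weighted_var(values: np.ndarray, counts: np.ndarray) -> float:
    n = counts.sum()
    m = (values * counts).sum() / n
    return float(((values - m) ** 2 * counts).sum() / (n - 1))


# ---------------------------------------------------------------------------
# One-sample statistics
# ---------------------------------------------------------------------------

def _one_sample_from_view(view: DatasetView, pop: str) -> np.ndarray:
    nal, het, var, mgw = [], [], [], []
    for values, pl in zip(view.locus_values, view.pop_locus[pop]):
        cnt = pl.allele_counts
        n = pl.n_copies
        if n == 0:
            continue
        present = cnt > 0
        k = int(present.sum())
        vals = values[present]
        nal.append(k)
        mgw.append(k / (vals.max() - vals.min() + 1))
        if n >= 2:
            p = cnt[present] / n
            het.append(n / (n - 1) * (1.0 - float(p @ p)))
            var.append(_weighted_var(vals, cnt[present]))
    if not nal:
        raise ValueError(f"population {pop!r} has no usable locus")
    return np.array(
        [np.mean(nal), np.mean(het) if het else 0.0,
         np.mean(var) if var else 0.0, np.mean(mgw)]
    )


def one_sample_stats(dataset: GenotypeDataset, pop: str) -> dict[str, float]:
    """Mean allele count, unbiased gene diversity, allele-size variance and
    Garza–Williamson M for one population, averaged over usable loci."""
    if pop not in dataset.populations:
        raise KeyError(pop)
    vals = _one_sample_from_view(DatasetView(dataset), pop)
    return dict(zip(ONE_SAMPLE_STATS, vals.tolist()))


# ---------------------------------------------------------------------------
# Two-sample statistics
# ---------------------------------------------------------------------------

def _wc_components(
    values: np.ndarray, pls: list[_PopLocus]
) -> tuple[float, float, float]:
    """Weir–Cockerham (1984) variance components a, b, c summed over the
    alleles of one locus, for r = len(pls) populations."""
    r = len(pls)
    n_i = np.array([pl.n_ind for pl in pls], dtype=float)
    if np.any(n_i < 1) or n_i.sum() < 2:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    p_i = np.stack([pl.allele_counts / pl.n_copies for pl in pls])  # (r, K)
    h_i = np.stack([pl.het_counts() / pl.n_ind for pl in pls])
    pbar = (n_i[:, None] * p_i).sum(0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_fst(dataset: GenotypeDataset, pops: list[str] | None = None) -> float:
    """Multi-locus Weir–Cockerham theta: sum of a components over the sum of
    a + b + c across alleles and loci (raw; may be negative or NaN when no
    variation is present)."""
    view = DatasetView(dataset)
    pops = pops or view.pops
    num = den = 0.0
    for j, values in enumerate(view.locus_values):
        pls = [view.pop_locus[p][j] for p in pops]
        if any(pl.n_ind == 0 for pl in pls) or len(values) < 2:
            continue
        a, b, c = _wc_components(values, pls)
        num += a
        den += a + b + c
    return num / den if den != 0.0 else float("nan")


def _fst_from_view(view: DatasetView, a: str, b: str) -> float:
    num = den = 0.0
    for j, values in enumerate(view.locus_values):
        pa, pb = view.pop_locus[a][j], view.pop_locus[b][j]
        if pa.n_ind == 0 or pb.n_ind == 0 or len(values) < 2:
            continue
        ca, cb, cc = _wc_components(values, [pa, pb])
        num += ca
        den += ca + cb + cc
    return num / den if den != 0.0 else float("nan")


def _assignment_loglik(
    values: np.ndarray, pl_from: _PopLocus, pl_to: _PopLocus
) -> list[float]:
    """Per-individual log-likelihood of ``pl_from`` genotypes under the
    allele frequencies of ``pl_to`` (add-one smoothing over the locus's
    allele support, so private alleles never hit log 0)."""
    if pl_to.n_copies == 0 or pl_from.n_ind == 0:
        return []
    support = int((pl_from.allele_counts + pl_to.allele_counts > 0).sum())
    lp = np.log((pl_to.allele_counts + 1.0) / (pl_to.n_copies + support))
    C = pl_from.indiv_counts
    het = (C == 1).any(axis=1)  # genotype prob: p^2 or 2*p_a*p_b
    return (C @ lp + np.log(2.0) * het).tolist()


def _pair_stats_from_view(view: DatasetView, a: str, b: str) -> np.ndarray:
    n2p, h2p, v2p = [], [], []
    fst_num = fst_den = 0.0
    lik_ab: dict[int, list[float]] = {}
    lik_ba: dict[int, list[float]] = {}
    das_sum = das_n = 0
    dm2 = []
    for j, values in enumerate(view.locus_values):
        pa, pb = view.pop_locus[a][j], view.pop_locus[b][j]
        if pa.n_copies == 0 or pb.n_copies == 0:
            continue
        cnt = pa.allele_counts + pb.allele_counts
        n = pa.n_copies + pb.n_copies
        present = cnt > 0
        vals = values[present]
        n2p.append(int(present.sum()))
        if n >= 2:
            p = cnt[present] / n
            h2p.append(n / (n - 1) * (1.0 - float(p @ p)))
            v2p.append(_weighted_var(vals, cnt[present]))
        if len(values) >= 2:
            ca, cb, cc = _wc_components(values, [pa, pb])
            fst_num += ca
            fst_den += ca + cb + cc
        for store, src, dst in ((lik_ab, pa, pb), (lik_ba, pb, pa)):
            for i, ll in enumerate(_assignment_loglik(values, src, dst)):
                store.setdefault(i, []).append(ll)
        # shared-allele distance over all across-population individual pairs
        shared = np.minimum(
            pa.indiv_counts[:, None, :], pb.indiv_counts[None, :, :]
        ).sum(axis=2)
        das_sum += shared.sum() / 2.0
        das_n += shared.size
        ma = (values * pa.allele_counts).sum() / pa.n_copies
        mb = (values * pb.allele_counts).sum() / pb.n_copies
        dm2.append((ma - mb) ** 2)
    if not n2p:
        raise ValueError(f"no locus usable in both {a!r} and {b!r}")
    fst = fst_num / fst_den if fst_den != 0.0 else float("nan")
    likab = np.mean([np.sum(v) for v in lik_ab.values()]) if lik_ab else float("nan")
    likba = np.mean([np.sum(v) for v in lik_ba.values()]) if lik_ba else float("nan")
    das = 1.0 - das_sum / das_n if das_n else float("nan")
    return np.array(
        [np.mean(n2p), np.mean(h2p) if h2p else 0.0,
         np.mean(v2p) if v2p else 0.0, fst, likab, likba, das, np.mean(dm2)]
    )


def two_sample_stats(dataset: GenotypeDataset, a: str, b: str) -> dict[str, float]:
    """The eight pairwise statistics for populations ``a`` and ``b``."""
    vals = _pair_stats_from_view(DatasetView(dataset), a, b)
    return dict(zip(TWO_SAMPLE_STATS, vals.tolist()))


# ---------------------------------------------------------------------------
# Three-sample statistic (admixture coefficient)
# ---------------------------------------------------------------------------

def _aml_from_view(
    view: DatasetView, admixed: str, s1: str, s2: str
) -> tuple[float, bool]:
    per_locus: list[float] = []
    for j, values in enumerate(view.locus_values):
        pm, p1, p2 = (
            view.pop_locus[p][j] for p in (admixed, s1, s2)
        )
        if min(pm.n_copies, p1.n_copies, p2.n_copies) == 0:
            continue
        fm = pm.allele_counts / pm.n_copies
        f1 = p1.allele_counts / p1.n_copies
        f2 = p2.allele_counts / p2.n_copies
        d = f1 - f2
        den = float(d @ d)
        if den == 0.0:
            continue
        r = float(d @ (fm - f2)) / den
        per_locus.append(min(1.0, max(0.0, r)))
    if not per_locus:
        return 0.5, True
    return float(np.mean(per_locus)), False


def three_sample_stats(
    dataset: GenotypeDataset, admixed: str, s1: str, s2: str
) -> tuple[float, bool]:
    """Least-squares admixture coefficient: the fraction of the admixed gene
    pool contributed by ``s1``, estimated per locus by projecting the admixed
    allele frequencies onto the source-frequency segment, clipped to [0, 1]
    and averaged over informative loci. The flag is True when the sources are
    indistinguishable at every locus (value falls back to 0.5)."""
    if len({admixed, s1, s2}) != 3:
        raise ValueError("admixed and source populations must be distinct")
    return _aml_from_view(DatasetView(dataset), admixed, s1, s2)


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------

def _triplet_list(
    pops: list[str], triplets: str | list[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    if triplets == "all":
        out = []
        for a, b, c in itertools.combinations(pops, 3):
            out.extend([(a, b, c), (b, a, c), (c, a, b)])  # target first
        return out
    for t in triplets:
        for p in t:
            if p not in pops:
                raise KeyError(f"triplet references unknown population {p!r}")
        if len(set(t)) != 3:
            raise ValueError(f"triplet {t} has repeated populations")
    return [tuple(t) for t in triplets]


def catalog_names(
    pops: list[str], triplets: str | list[tuple[str, str, str]] = "all"
) -> tuple[list[str], list[int]]:
    """Deterministic full-catalog names and arities for the population list."""
    names: list[str] = []
    arity: list[int] = []
    for stat in ONE_SAMPLE_STATS:
        for p in pops:
            names.append(f"{stat}_{p}")
            arity.append(1)
    pairs = list(itertools.combinations(pops, 2))
    for stat in TWO_SAMPLE_STATS:
        for a, b in pairs:
            names.append(f"{stat}_{a}_{b}")
            arity.append(2)
    for t, s1, s2 in _triplet_list(pops, triplets):
        names.append(f"AML_{t}_{s1}_{s2}")
        arity.append(3)
    return names, arity


def full_catalog(
    dataset: GenotypeDataset, triplets: str | list[tuple[str, str, str]] = "all"
) -> StatVector:
    """Compute the full catalog: 4P + 8·C(P,2) + 3·C(P,3) statistics."""
    view = DatasetView(dataset)
    pops = view.pops
    names, arity = catalog_names(pops, triplets)
    one = {p: _one_sample_from_view(view, p) for p in pops}
    values: list[float] = []
    for k in range(len(ONE_SAMPLE_STATS)):
        values.extend(one[p][k] for p in pops)
    pairs = list(itertools.combinations(pops, 2))
    pair_vals = {pair: _pair_stats_from_view(view, *pair) for pair in pairs}
    for k in range(len(TWO_SAMPLE_STATS)):
        values.extend(pair_vals[pair][k] for pair in pairs)
    degenerate = []
    for t, s1, s2 in _triplet_list(pops, triplets):
        v, flag = _aml_from_view(view, t, s1, s2)
        if flag:
            degenerate.append((t, s1, s2))
        values.append(v)
    if degenerate:
        warnings.warn(
            f"AML sources indistinguishable for triplets {degenerate}; "
            "reported 0.5",
            stacklevel=2,
        )
    return StatVector(names, np.array(values), arity)


def _canonical_triplets(
    pops: list[str], triplets: list[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    """Order each declared triplet's two sources by population order, so the
    names coincide with the full catalog's arrangement names (AML with
    swapped sources is the complementary fraction; as a covariate the
    orientation is conventional)."""
    order = {p: i for i, p in enumerate(pops)}
    out = []
    for t, s1, s2 in _triplet_list(pops, triplets):
        if order[s1] > order[s2]:
            s1, s2 = s2, s1
        out.append((t, s1, s2))
    return out


def estimation_subset_names(
    pops: list[str], triplets: list[tuple[str, str, str]]
) -> tuple[list[str], list[int]]:
    """Names of the reduced estimation set: 2P + C(P,2) + T statistics."""
    names: list[str] = []
    arity: list[int] = []
    for stat in ("NAL", "HET"):
        for p in pops:
            names.append(f"{stat}_{p}")
            arity.append(1)
    for a, b in itertools.combinations(pops, 2):
        names.append(f"FST_{a}_{b}")
        arity.append(2)
    for t, s1, s2 in _canonical_triplets(pops, triplets):
        names.append(f"AML_{t}_{s1}_{s2}")
        arity.append(3)
    return names, arity


def estimation_subset(
    dataset: GenotypeDataset, triplets: list[tuple[str, str, str]]
) -> StatVector:
    """Compute the reduced estimation statistic set on a dataset."""
    view = DatasetView(dataset)
    pops = view.pops
    names, arity = estimation_subset_names(pops, triplets)
    values: list[float] = []
    one = {p: _one_sample_from_view(view, p) for p in pops}
    values.extend(one[p][0] for p in pops)
    values.extend(one[p][1] for p in pops)
    for a, b in itertools.combinations(pops, 2):
        values.append(_fst_from_view(view, a, b))
    for t, s1, s2 in _canonical_triplets(pops, triplets):
        values.append(_aml_from_view(view, t, s1, s2)[0])
    return StatVector(names, np.array(values), arity)
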