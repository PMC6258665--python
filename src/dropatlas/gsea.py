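"""Preranked gene set enrichment analysis.

Given a ranked gene list (here: the log2FC marker metric) and a GMT
gene-set collection, each set is scored with the weighted
Kolmogorov-Smirnov-style running sum: walking the ranking, genes in
the set increment the sum by |score|^p / sum of |score|^p over the
set's genes, genes outside it decrement by 1/(N - set size).  The
enrichment score (ES) is the signed maximum deviation of the walk.

Significance comes from a permutation null of random gene sets of
matched size drawn from the ranked universe (the standard preranked
convention; phenotype permutation is not possible from a ranked list
alone).  NES divides ES by the mean |null ES| of the same sign, the
permutation p uses add-one smoothing, and the FDR q is the
sign-stratified ratio of null to observed NES tail fractions, clamped
to [0, 1] and made monotone.  Reporting follows the convention that
only upregulated sets (ES > 0) can be significant (FDR < cutoff);
down-regulated sets are reported with FDR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GMTFormatError(ValueError):
    """Raised for malformed GMT gene-set files."""


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as parsed from GMT."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise GMTFormatError(f"set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RankedList:
    """Genes ordered by descending score, ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, genes, scores) -> "RankedList":
        genes = [str(g) for g in genes]
        if len(set(genes)) != len(genes):
            raise ValueError("ranked list genes must be unique")
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        return cls(
            genes=[genes[i] for i in order], scores=scores[order]
        )

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls.from_scores(list(s.index), s.to_numpy())

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaSetResult:
    """Enrichment outcome for one gene set."""

    name: str
    size_used: int
    ES: float
    NES: float = float("nan")
    p_perm: float = float("nan")
    FDR_q: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    reported_FDR: float = float("nan")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ...

    Duplicate genes within a set are collapsed (first occurrence kept)
    with a warning entry in the description; duplicate set names or
    lines with fewer than three fields are errors.
    """
    import warnings

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTFormatError(
                f"{path}:{lineno}: expected at least 3 tab-separated fields"
            )
        name, desc, genes = fields[0], fields[1], fields[2:]
        genes = [g for g in genes if g]
        if name in sets:
            raise GMTFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen, unique = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        if len(unique) != len(genes):
            warnings.warn(
                f"set {name!r}: {len(genes) - len(unique)} duplicate genes collapsed",
                stacklevel=2,
            )
        sets[name] = unique
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join(
            [name, collection.descriptions.get(name, "")] + list(genes)
        )
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrichment_score(
    ranked: RankedList,
    gene_set,
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of one gene set.

    Returns (ES, running profile over the full ranking, leading-edge
    genes).  Hits increment the running sum by |score|^p normalized by
    the summed hit weights; misses decrement by 1/(N - set size); ES is
    the signed maximum deviation, and the leading edge is the hit genes
    between the start of the walk and its extremum (from the extremum
    to the end for negative ES).
    """
    n = len(ranked)
    member = np.isin(np.asarray(ranked.genes, dtype=object), list(gene_set))
    m = int(member.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if m == n:
        raise ValueError("gene set equals the full ranked list")
    weights = np.abs(ranked.scores) ** weight_p
    hit_w = np.where(member, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit > 0:
        inc = hit_w / total_hit
    else:  # all member scores zero: equal hit increments
        inc = np.where(member, 1.0 / m, 0.0)
    dec = np.where(member, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [g for g, hit in zip(ranked.genes[: i_max + 1], member[: i_max + 1]) if hit]
    else:
        es = float(running[i_min])
        leading = [g for g, hit in zip(ranked.genes[i_min:], member[i_min:]) if hit]
    return es, running, leading


def _null_es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """ES for many random sets given their sorted hit positions.

    The running sum only attains extrema adjacent to hit positions, so
    for each sampled set it suffices to evaluate the walk just after
    and just before each hit.
    """
    n_perm, m = positions.shape
    w = weights[positions]  # (n_perm, m)
    cum_w = np.cumsum(w, axis=1)
    total = cum_w[:, -1:]
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_after = np.where(zero_total, (np.arange(1, m + 1) / m)[None, :], cum_w / np.where(total == 0, 1, total))
    frac_before = frac_after - np.where(
        zero_total, 1.0 / m, w / np.where(total == 0, 1, total)
    )
    miss_step = 1.0 / (n - m)
    j = np.arange(m)[None, :]
    # misses before rank pos (exclusive) = pos - j; inclusive = pos + 1 - (j+1)
    after = frac_after - (positions - j) * miss_step
    before = frac_before - (positions - j) * miss_step
    max_pos = after.max(axis=1)
    min_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_pos >= -min_neg, max_pos, min_neg)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 10000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> np.ndarray:
    """Null ES sample from random gene sets of matched size.

    Each permutation draws ``set_size`` genes uniformly without
    replacement from the ranked universe and records the resulting ES.
    Reproducible for a fixed seed; intended to be cached and shared
    across observed sets of equal size.
    """
    n = len(ranked)
    if set_size >= n:
        raise ValueError("set size must be smaller than the ranked universe")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** weight_p
    out = np.empty(n_perm)
    chunk = max(1, int(2e7) // max(n, 1))
    start = 0
    while start < n_perm:
        size = min(chunk, n_perm - start)
        u = rng.random((size, n))
        positions = np.sort(
            np.argpartition(u, set_size, axis=1)[:, :set_size], axis=1
        )
        out[start : start + size] = _null_es_from_positions(positions, weights, n)
        start += size
    return out


class NullCache:
    """Shared permutation nulls keyed by set size."""

    def __init__(self, ranked: RankedList, n_perm: int, seed: int, weight_p: float = 1.0):
        self.ranked = ranked
        self.n_perm = n_perm
        self.seed = seed
        self.weight_p = weight_p
        self._cache: dict[int, np.ndarray] = {}

    def get(self, set_size: int) -> np.ndarray:
        if set_size not in self._cache:
            # derive a per-size stream so caching order cannot matter
            self._cache[set_size] = permutation_null(
                self.ranked,
                set_size,
                n_perm=self.n_perm,
                seed=(self.seed * 100003 + set_size) % (2**31),
                weight_p=self.weight_p,
            )
        return self._cache[set_size]


def nes_and_fdr(
    results: list[GseaSetResult],
    nulls: dict[int, np.ndarray],
) -> list[GseaSetResult]:
    """Attach NES, permutation p and sign-stratified FDR q to results.

    NES = ES / mean(|null ES| of the same sign); p = add-one-smoothed
    fraction of same-sign null ES at least as extreme; FDR q is the
    ratio of the null NES tail fraction to the observed NES tail
    fraction within each sign stratum, clamped to [0, 1] and made
    monotone in |NES|.
    """
    # per-size normalization means
    norm_means: dict[int, tuple[float, float]] = {}
    null_nes_all: list[np.ndarray] = []
    for size, null in nulls.items():
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = float(pos.mean()) if pos.size else float("nan")
        mean_neg = float(np.abs(neg).mean()) if neg.size else float("nan")
        norm_means[size] = (mean_pos, mean_neg)
        nes = np.where(null >= 0, null / mean_pos if pos.size else np.nan,
                       null / mean_neg if neg.size else np.nan)
        null_nes_all.append(nes[np.isfinite(nes)])
    null_nes = np.concatenate(null_nes_all) if null_nes_all else np.array([])

    for r in results:
        null = nulls[r.size_used]
        mean_pos, mean_neg = norm_means[r.size_used]
        if r.ES >= 0:
            same = null[null > 0]
            r.NES = r.ES / mean_pos if np.isfinite(mean_pos) else float("nan")
        else:
            same = null[null < 0]
            r.NES = r.ES / mean_neg if np.isfinite(mean_neg) else float("nan")
        if same.size:
            extreme = int(np.sum(np.abs(same) >= abs(r.ES)))
            r.p_perm = (1 + extreme) / (1 + same.size)
        else:
            r.p_perm = float("nan")

    obs_nes = np.array([r.NES for r in results])
    null_pos = null_nes[null_nes >= 0]
    null_neg = null_nes[null_nes < 0]
    obs_pos = obs_nes[obs_nes >= 0]
    obs_neg = obs_nes[obs_nes < 0]
    for r in results:
        if not np.isfinite(r.NES):
            r.FDR_q = float("nan")
            continue
        if r.NES >= 0:
            null_tail = np.mean(null_pos >= r.NES) if null_pos.size else np.nan
            obs_tail = np.mean(obs_pos >= r.NES) if obs_pos.size else np.nan
        else:
            null_tail = np.mean(null_neg <= r.NES) if null_neg.size else np.nan
            obs_tail = np.mean(obs_neg <= r.NES) if obs_neg.size else np.nan
        if not np.isfinite(null_tail) or not np.isfinite(obs_tail) or obs_tail == 0:
            r.FDR_q = float("nan")
            continue
        r.FDR_q = float(min(1.0, null_tail / obs_tail))
    # monotone adjustment: q non-increasing as |NES| grows, per sign
    for sign in (1, -1):
        stratum = [
            r for r in results
            if np.isfinite(r.NES) and np.isfinite(r.FDR_q)
            and (r.NES >= 0) == (sign == 1)
        ]
        stratum.sort(key=lambda r: abs(r.NES), reverse=True)
        running = np.inf
        for r in stratum:
            running = min(running, r.FDR_q)
            r.FDR_q = running
    return results


def prerank(
    ranked: RankedList,
    collection: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 10000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> tuple[list[GseaSetResult], list[dict]]:
    """Score every set of a collection against a ranked list.

    Returns (results, skipped): sets whose intersection with the
    ranked universe falls outside [min_size, max_size] are skipped
    with a record, not silently dropped.
    """
    universe = set(ranked.genes)
    results: list[GseaSetResult] = []
    skipped: list[dict] = []
    cache = NullCache(ranked, n_perm=n_perm, seed=seed, weight_p=weight_p)
    sizes_needed = []
    for name in sorted(collection.sets):
        genes = [g for g in collection.sets[name] if g in universe]
        if not min_size <= len(genes) <= max_size:
            skipped.append(
                {"set": name, "size_used": len(genes), "reason": "size out of range"}
            )
            continue
        es, _, leading = enrichment_score(ranked, genes, weight_p=weight_p)
        results.append(
            GseaSetResult(
                name=name, size_used=len(genes), ES=es, leading_edge=leading
            )
        )
        sizes_needed.append(len(genes))
    nulls = {size: cache.get(size) for size in sorted(set(sizes_needed))}
    if results:
        nes_and_fdr(results, nulls)
    return results, skipped


def report(
    results: list[GseaSetResult],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Apply the up-regulation-only reporting convention.

    Upregulated sets (ES > 0) are significant iff FDR q < cutoff
    (strict inequality); every down-regulated set (ES < 0) carries
    reported_FDR = 1 regardless of its q.
    """
    rows = []
    for r in results:
        if r.ES < 0:
            r.reported_FDR = 1.0
        else:
            r.reported_FDR = r.FDR_q
        rows.append(
            {
                "set": r.name,
                "size_used": r.size_used,
                "ES": r.ES,
                "NES": r.NES,
                "p_perm": r.p_perm,
                "FDR_q": r.FDR_q,
                "reported_FDR": r.reported_FDR,
                "significant": bool(
                    r.ES > 0 and np.isfinite(r.FDR_q) and r.FDR_q < fdr_cutoff
                ),
                "leading_edge": ",".join(r.leading_edge),
            }
        )
    return pd.DataFrame(rows)


def fdr_matrix(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Heat-map-ready matrix of reported FDR per (set, condition)."""
    cols = {}
    for label, rep in reports.items():
        cols[label] = rep.set_index("set")["reported_FDR"]
    return pd.DataFrame(cols)
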