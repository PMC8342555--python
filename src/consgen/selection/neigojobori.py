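"""Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction and a
codon-resampling bootstrap Z-test for positive selection.

Synonymous/nonsynonymous sites use the fraction-of-changes convention
with changes to stop codons excluded and weights renormalized;
multi-step codon differences average over all substitution pathways
with equal weight, excluding pathways through stop codons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from consgen.selection.alignment import (
    CODON_TO_AA,
    STOP_CODONS,
    CodonAlignment,
    partition_alignment,
)

_BASES = "ACGT"


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p = {p:.4f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> "tuple[float, float]":
    """(synonymous, nonsynonymous) site counts for one codon."""
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            syn += CODON_TO_AA[alt] == aa
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> "tuple[float, float]":
    """(synonymous, nonsynonymous) differences by pathway enumeration.

    All substitution orders between the two codons are weighted equally;
    pathways through stop codons are excluded and weights renormalized.
    If every pathway is blocked, stop-intermediate pathways are allowed
    back in as a fallback.
    """
    for c in (c1, c2):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c}")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if nxt in STOP_CODONS:
                # count the step by codon identity; stops have no amino acid
                nonsyn += 1
            else:
                syn += CODON_TO_AA.get(cur, None) == CODON_TO_AA.get(nxt, None)
                nonsyn += CODON_TO_AA.get(cur) != CODON_TO_AA.get(nxt)
            cur = nxt
        return syn, nonsyn

    for allow_stops in (False, True):
        results = [
            r for r in (walk(o, allow_stops)
                        for o in itertools.permutations(diff_pos))
            if r is not None
        ]
        if results:
            sd = sum(r[0] for r in results) / len(results)
            nd = sum(r[1] for r in results) / len(results)
            return sd, nd
    raise AssertionError("unreachable")


@dataclass
class DnDsResult:
    partition: str
    dN: float
    dS: float
    omega: float            # dN/dS; inf when dS == 0 and dN > 0, nan when both 0
    se_dN: float
    se_dS: float
    z: float
    p_value: float          # one-tailed P(dN <= dS) rejection level
    n_sequences: int
    n_codons: int
    bootstrap: int


def _pair_columns(aln: CodonAlignment):
    """Per-pair, per-codon-column site and difference arrays."""
    codon_lists = [aln.codons(i) for i in range(len(aln.sequences))]
    site_arr = np.array(
        [[codon_sites(c) for c in codons] for codons in codon_lists]
    )  # (n_seq, L, 2)
    pairs = list(itertools.combinations(range(len(codon_lists)), 2))
    L = aln.n_codons
    S = np.empty((len(pairs), L))
    N = np.empty((len(pairs), L))
    SD = np.empty((len(pairs), L))
    ND = np.empty((len(pairs), L))
    for k, (i, j) in enumerate(pairs):
        S[k] = (site_arr[i, :, 0] + site_arr[j, :, 0]) / 2.0
        N[k] = (site_arr[i, :, 1] + site_arr[j, :, 1]) / 2.0
        for l in range(L):
            SD[k, l], ND[k, l] = codon_differences(codon_lists[i][l],
                                                   codon_lists[j][l])
    return S, N, SD, ND


def _mean_distances(S, N, SD, ND, strict: bool):
    """Mean JC-corrected dN and dS over pairs given per-pair totals."""
    s_tot, n_tot = S.sum(axis=-1), N.sum(axis=-1)
    ps = np.divide(SD.sum(axis=-1), s_tot, out=np.zeros_like(s_tot),
                   where=s_tot > 0)
    pn = np.divide(ND.sum(axis=-1), n_tot, out=np.zeros_like(n_tot),
                   where=n_tot > 0)
    if strict:
        bad = np.nonzero(np.maximum(ps, pn) >= 0.75)[0]
        if bad.size:
            raise ValueError(
                f"Jukes-Cantor correction undefined for sequence pair index "
                f"{int(bad[0])} (p >= 0.75)"
            )
        ds = np.array([jukes_cantor(v) for v in np.atleast_1d(ps)])
        dn = np.array([jukes_cantor(v) for v in np.atleast_1d(pn)])
        return float(dn.mean()), float(ds.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        ds = -0.75 * np.log1p(-4.0 * ps / 3.0)
        dn = -0.75 * np.log1p(-4.0 * pn / 3.0)
    return float(np.nanmean(dn)), float(np.nanmean(ds))


def nei_gojobori(
    aln: CodonAlignment,
    partition: str = "all",
    bootstrap: int = 2000,
    seed: "int | None" = None,
) -> DnDsResult:
    """Overall dN/dS (mean over all unique sequence pairs) with a
    one-tailed bootstrap Z-test of dN > dS.

    ``partition`` is ``all``, ``pbr`` or ``non_pbr``; the latter two
    subset codons by the alignment's ``pbr_mask``.
    """
    if len(aln.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if partition not in ("all", "pbr", "non_pbr"):
        raise ValueError(f"unknown partition {partition!r}")
    if partition != "all":
        pbr, non_pbr = partition_alignment(aln)
        sub = pbr if partition == "pbr" else non_pbr
        if sub is None:
            raise ValueError(f"partition {partition!r} is empty")
        aln = sub

    S, N, SD, ND = _pair_columns(aln)
    dn, ds = _mean_distances(S, N, SD, ND, strict=True)

    L = aln.n_codons
    rng = np.random.default_rng(seed)
    # column multiplicities for all replicates at once -> BLAS mat-mults
    idx = rng.integers(0, L, size=(bootstrap, L))
    M = np.zeros((L, bootstrap))
    for b in range(bootstrap):
        np.add.at(M[:, b], idx[b], 1.0)
    s_tot = S @ M
    n_tot = N @ M
    sd_tot = SD @ M
    nd_tot = ND @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(s_tot > 0, sd_tot / s_tot, 0.0)
        pn = np.where(n_tot > 0, nd_tot / n_tot, 0.0)
        ds_b = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * ps / 3.0), np.nan)
        dn_b = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * pn / 3.0), np.nan)
    import warnings

    with warnings.catch_warnings():
        # replicates where every pair falls outside the JC domain give
        # all-NaN columns; they are dropped below
        warnings.simplefilter("ignore", RuntimeWarning)
        dn_reps = np.nanmean(dn_b, axis=0)
        ds_reps = np.nanmean(ds_b, axis=0)
    ok = np.isfinite(dn_reps) & np.isfinite(ds_reps)
    se_dn = float(dn_reps[ok].std(ddof=1)) if ok.sum() > 1 else 0.0
    se_ds = float(ds_reps[ok].std(ddof=1)) if ok.sum() > 1 else 0.0

    var = se_dn**2 + se_ds**2
    if var > 0:
        z = (dn - ds) / math.sqrt(var)
        p = float(norm.sf(z))
    else:
        z, p = 0.0, 1.0
    omega = dn / ds if ds > 0 else (math.inf if dn > 0 else math.nan)
    return DnDsResult(
        partition, dn, ds, omega, se_dn, se_ds, z, p,
        len(aln.sequences), L, bootstrap,
    )
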