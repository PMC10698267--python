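"""ABBA-BABA / Patterson's D introgression test with delete-one jackknife.

For four populations with the relationship (((P1, P2), P3), O), the test
contrasts the two discordant allele-sharing patterns.  With per-population
derived-allele frequencies (ancestral state polarised by the outgroup's
major allele) the frequency-weighted per-locus pattern probabilities are

    abba_l = (1 - p1) * p2 * p3 * (1 - pO)
    baba_l = p1 * (1 - p2) * p3 * (1 - pO)

and D = (sum abba - sum baba) / (sum abba + sum baba).  Frequency weighting
yields non-integer pattern "counts".  Significance comes from a
delete-one-locus jackknife (the loci are unlinked array SNPs, so each locus
is its own block): Z = D / SE, two-sided normal p.  A significantly positive
D indicates introgression from P3 into P2; a significantly negative D an
excess of shared ancestry between P1 and P3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, allele_frequencies


@dataclass
class DStatResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    c_abba: float
    c_baba: float
    d: float                 # NaN when undefined (no informative loci)
    se: float
    z: float
    p_value: float
    direction: str
    n_loci_used: int
    per_locus_abba: np.ndarray
    per_locus_baba: np.ndarray
    flagged_outgroup_loci: int  # outgroup minor-allele freq > 0.5 impossible; >0 polymorphic

    @property
    def mean_abba_per_locus(self) -> float:
        return self.c_abba / self.n_loci_used if self.n_loci_used else np.nan

    @property
    def mean_baba_per_locus(self) -> float:
        return self.c_baba / self.n_loci_used if self.n_loci_used else np.nan


def abba_baba(
    panel: GenotypePanel, p1: str, p2: str, p3: str, outgroup: str,
    alpha: float = 0.05,
) -> DStatResult:
    """Frequency-weighted Patterson's D for one population trio plus outgroup."""
    freq = {pop: allele_frequencies(panel, pop) for pop in (p1, p2, p3, outgroup)}
    f_o = freq[outgroup]
    usable = ~np.isnan(f_o)
    for pop in (p1, p2, p3):
        usable &= ~np.isnan(freq[pop])
    if usable.sum() < 2:
        raise ValueError("need called data in all four populations at >= 2 shared loci")
    # polarise: ancestral allele = outgroup major allele
    derived_is_b = f_o[usable] <= 0.5
    flagged = int(((f_o[usable] > 0) & (f_o[usable] < 1)).sum())
    p = {}
    for pop in (p1, p2, p3, outgroup):
        fb = freq[pop][usable]
        p[pop] = np.where(derived_is_b, fb, 1 - fb)
    abba = (1 - p[p1]) * p[p2] * p[p3] * (1 - p[outgroup])
    baba = p[p1] * (1 - p[p2]) * p[p3] * (1 - p[outgroup])
    c_abba = float(abba.sum())
    c_baba = float(baba.sum())
    total = c_abba + c_baba
    if total == 0:
        d = np.nan
        se = z = p_value = np.nan
        direction = "undefined"
    else:
        d = (c_abba - c_baba) / total
        if int(((abba + baba) > 0).sum()) >= 3:
            se, z, p_value = jackknife_significance(abba, baba)
        else:  # too few informative loci for a jackknife
            se = z = p_value = np.nan
        direction = interpret_direction(d, p_value, alpha=alpha)
    return DStatResult(
        p1=p1, p2=p2, p3=p3, outgroup=outgroup,
        c_abba=c_abba, c_baba=c_baba, d=float(d), se=float(se), z=float(z),
        p_value=float(p_value), direction=direction,
        n_loci_used=int(usable.sum()),
        per_locus_abba=abba, per_locus_baba=baba,
        flagged_outgroup_loci=flagged,
    )


def jackknife_significance(
    abba: np.ndarray, baba: np.ndarray, block_size: int = 1
) -> tuple[float, float, float]:
    """Delete-one-block jackknife SE, Z and two-sided p for D.

    Blocks with zero total pattern weight are uninformative and excluded;
    at least 3 informative blocks are required.  A degenerate jackknife
    (all leave-one-out D identical) yields SE = 0 and p = NaN.
    """
    abba = np.asarray(abba, float)
    baba = np.asarray(baba, float)
    if block_size > 1:
        n_blocks = int(np.ceil(abba.size / block_size))
        abba = np.array([abba[i * block_size:(i + 1) * block_size].sum() for i in range(n_blocks)])
        baba = np.array([baba[i * block_size:(i + 1) * block_size].sum() for i in range(n_blocks)])
    informative = (abba + baba) > 0
    a, b = abba[informative], baba[informative]
    n = a.size
    if n < 3:
        raise ValueError(f"jackknife needs >= 3 informative blocks, got {n}")
    sa, sb = a.sum(), b.sum()
    d_loo = ((sa - a) - (sb - b)) / ((sa - a) + (sb - b))
    d_bar = d_loo.mean()
    se = float(np.sqrt((n - 1) / n * ((d_loo - d_bar) ** 2).sum()))
    d = (sa - sb) / (sa + sb)
    if se == 0:
        return 0.0, np.nan, np.nan
    z = d / se
    p = 2 * stats.norm.sf(abs(z))
    return se, float(z), float(p)


def interpret_direction(d: float, p_value: float, alpha: float = 0.05) -> str:
    """Direction label: excess ABBA (D>0) = gene flow P3 into P2; excess BABA
    (D<0) = excess shared ancestry between P1 and P3; otherwise none."""
    if np.isnan(p_value) or p_value >= alpha:
        return "none"
    return "P3->P2" if d > 0 else "P1-P3 shared ancestry"


def dstat_panel_sweep(
    panel: GenotypePanel, p3: str, outgroup: str,
    pairs: list[tuple[str, str]], alpha: float = 0.05,
) -> pd.DataFrame:
    """D-statistics for a list of (P1, P2) pairs against a fixed P3 and outgroup.

    Output mirrors the familiar ABBA/BABA table layout, with both raw
    weighted counts and per-locus means.
    """
    known = set(panel.populations)
    for pop in [p3, outgroup] + [p for pair in pairs for p in pair]:
        if pop not in known:
            raise KeyError(f"unknown population {pop!r}")
    rows = []
    for pa, pb in pairs:
        res = abba_baba(panel, pa, pb, p3, outgroup, alpha=alpha)
        rows.append(
            {
                "P1": pa, "P2": pb, "P3": p3, "outgroup": outgroup,
                "ABBA": res.c_abba, "BABA": res.c_baba,
                "ABBA_per_locus": res.mean_abba_per_locus,
                "BABA_per_locus": res.mean_baba_per_locus,
                "D": res.d, "SE": res.se, "Z": res.z, "p": res.p_value,
                "direction": res.direction, "n_loci": res.n_loci_used,
            }
        )
    columns = ["P1", "P2", "P3", "outgroup", "ABBA", "BABA", "ABBA_per_locus",
               "BABA_per_locus", "D", "SE", "Z", "p", "direction", "n_loci"]
    return pd.DataFrame(rows, columns=columns)
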