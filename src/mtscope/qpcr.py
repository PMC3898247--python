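"""Absolute qRT-PCR quantification and nonparametric group comparison.

The copy-number model inverts exponential amplification: a reaction with
per-cycle efficiency E multiplies template by (1+E) each cycle, so if the
fluorescence threshold Ft is crossed at cycle Ct, the initial template
amount (per amplicon base, to make targets with different amplicon sizes
comparable) is

    N0 = Ft * (1 + E)^(-Ct) / Amp

with Amp the amplicon length in bp.  Downstream processing:

* DNA contamination measured by RT-minus controls is subtracted (floored at
  zero);
* estimates are normalized to a positive-control target (default ``cox2``):
  each sample's control estimate divided by the smallest control estimate in
  the batch gives that sample's normalization factor, and every target in
  the sample is divided by it — so all control replicates map back to the
  common minimum;
* groups are compared with an exact Mann-Whitney rank-sum test (full
  enumeration of rank splits, midranks for ties) and an above-background
  call combines the direction of medians with the test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: enumerate all rank splits exactly up to this pooled size (C(14,7) = 3432)
EXACT_ENUMERATION_LIMIT = 14


def _normalize_efficiency(E: float) -> float:
    """Efficiencies quoted in percent (e.g. 95) are mapped to fractions."""
    if E > 1.5:
        warnings.warn(
            f"efficiency {E} looks like a percentage; dividing by 100",
            stacklevel=3,
        )
        return E / 100.0
    return E


def copy_number(Ft: float, E: float, Ct: float, Amp: float) -> float:
    """Initial template amount N0 = Ft * (1+E)^(-Ct) / Amp."""
    if Amp <= 0:
        raise ValueError("amplicon size must be positive")
    E = _normalize_efficiency(E)
    if E <= 0:
        raise ValueError("reaction efficiency must be positive")
    if Ft <= 0 or Ct < 0:
        raise ValueError("Ft must be positive and Ct non-negative")
    return Ft * (1.0 + E) ** (-Ct) / Amp


def subtract_dna_background(
    N0_plus: float, N0_minus: float | None
) -> float:
    """RT-minus (no reverse transcriptase) estimate removed, floored at 0."""
    if N0_plus < 0:
        raise ValueError("N0 must be non-negative")
    if N0_minus is None or (isinstance(N0_minus, float) and math.isnan(N0_minus)):
        warnings.warn(
            "missing RT-minus control; subtracting 0", stacklevel=2
        )
        return N0_plus
    if N0_minus < 0:
        raise ValueError("RT-minus estimate must be non-negative")
    return max(0.0, N0_plus - N0_minus)


# ---------------------------------------------------------------------------
# well tables

WELL_COLUMNS = [
    "target",
    "condition",
    "bio_rep",
    "tech_rep",
    "Ct",
    "Ft",
    "rt_minus_Ct",
]


def read_wells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    if "rt_minus_Ct" not in df.columns:
        df["rt_minus_Ct"] = np.nan
    key = df[["target", "condition", "bio_rep", "tech_rep"]]
    if key.duplicated().any():
        raise ValueError("duplicate replicate keys in well table")
    return df


def read_primers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("target", "E", "Amp"):
        if c not in df.columns:
            raise ValueError(f"primer table missing column {c!r}")
    df = df.copy()
    df["E"] = [_normalize_efficiency(float(e)) for e in df["E"]]
    return df


def estimate_copies(
    wells: pd.DataFrame, primers: pd.DataFrame
) -> pd.DataFrame:
    """Per-well copy estimates with RT-minus background subtraction.

    Adds ``N0_raw``, ``N0_dna`` and ``N0_corrected`` columns.
    """
    pm = primers.set_index("target")
    unknown = set(wells["target"]) - set(pm.index)
    if unknown:
        raise ValueError(f"no primer parameters for targets: {sorted(unknown)}")
    out = wells.copy()
    raw, dna, corr = [], [], []
    for row in out.itertuples(index=False):
        E = float(pm.loc[row.target, "E"])
        Amp = float(pm.loc[row.target, "Amp"])
        n0 = copy_number(row.Ft, E, row.Ct, Amp)
        if row.rt_minus_Ct is None or pd.isna(row.rt_minus_Ct):
            n0_dna = 0.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n0_corr = subtract_dna_background(n0, None)
        else:
            n0_dna = copy_number(row.Ft, E, float(row.rt_minus_Ct), Amp)
            n0_corr = subtract_dna_background(n0, n0_dna)
        raw.append(n0)
        dna.append(n0_dna)
        corr.append(n0_corr)
    out["N0_raw"] = raw
    out["N0_dna"] = dna
    out["N0_corrected"] = corr
    return out


def normalize_to_control(
    estimates: pd.DataFrame, control_target: str = "cox2"
) -> pd.DataFrame:
    """Divide every sample by its control-derived normalization factor.

    Within each condition, factor_s = control_s / min(control); every target
    sharing replicate key s is divided by factor_s, so the control replicates
    all land on the batch minimum.  Samples without a control well are
    dropped with a warning; a zero or negative control value is a hard error.
    """
    out = estimates.reset_index(drop=True).copy()
    out["N0_normalized"] = np.nan
    keep = np.ones(len(out), dtype=bool)
    for cond, grp in out.groupby("condition"):
        ctrl = grp[grp["target"] == control_target]
        if ctrl.empty:
            warnings.warn(
                f"condition {cond!r}: no {control_target!r} wells; dropped",
                stacklevel=2,
            )
            keep[grp.index] = False
            continue
        if (ctrl["N0_corrected"] <= 0).any():
            raise ValueError(
                f"condition {cond!r}: control estimates must be positive"
            )
        cmin = float(ctrl["N0_corrected"].min())
        factors = {
            (r.bio_rep, r.tech_rep): float(r.N0_corrected) / cmin
            for r in ctrl.itertuples(index=False)
        }
        for idx, r in grp.iterrows():
            key = (r["bio_rep"], r["tech_rep"])
            if key not in factors:
                warnings.warn(
                    f"condition {cond!r}, replicate {key}: no control well; "
                    "replicate dropped",
                    stacklevel=2,
                )
                keep[idx] = False
                continue
            out.at[idx, "N0_normalized"] = r["N0_corrected"] / factors[key]
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact Mann-Whitney rank-sum test


@dataclass(frozen=True)
class RankSumResult:
    U: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # 'exact' or 'normal_approx'

    def __post_init__(self) -> None:
        if not 0 <= self.U <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0 < self.p_two_sided <= 1:
            raise ValueError("p outside (0, 1]")


def rank_sum_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Mann-Whitney test, exact for small samples.

    For pooled sizes up to :data:`EXACT_ENUMERATION_LIMIT` (covering the
    n = 6 vs 6 design of a 3-biological x 2-technical replicate experiment)
    the p-value is computed by full enumeration of all C(n1+n2, n1) rank
    splits of the observed pooled values, which is permutation-exact under
    ties (midranks).  Larger samples fall back to the normal approximation
    and are flagged ``normal_approx``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        n = n1 + n2
        extreme = 0
        total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                extreme += 1
        p = extreme / total
        return RankSumResult(
            U=u_obs, p_two_sided=p, n1=n1, n2=n2, method="exact"
        )

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(
        U=u_obs,
        p_two_sided=float(res.pvalue),
        n1=n1,
        n2=n2,
        method="normal_approx",
    )


def call_above_background(
    target_values: Sequence[float],
    background_values: Sequence[float],
    alpha: float = 0.05,
) -> dict[str, object]:
    """Is a target expressed above the background region?

    True when the target median exceeds the background median AND the
    two-sided rank-sum p is below ``alpha`` — direction and significance
    both required.
    """
    res = rank_sum_test(target_values, background_values)
    above = (
        float(np.median(target_values)) > float(np.median(background_values))
        and res.p_two_sided < alpha
    )
    return {
        "is_above": bool(above),
        "p": res.p_two_sided,
        "U": res.U,
        "median_target": float(np.median(target_values)),
        "median_background": float(np.median(background_values)),
    }


def call_polysome_association(
    pellet_target: Sequence[float],
    pellet_background: Sequence[float],
    alpha: float = 0.05,
) -> dict[str, object]:
    """Polysome association = above background within the pellet fraction.

    An EDTA-treated control of a truly associated target releases ribosomes
    and is expected to come back negative; run it through the same call.
    """
    return call_above_background(pellet_target, pellet_background, alpha)
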