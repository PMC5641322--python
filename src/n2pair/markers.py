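"""Cross-well molecular and lipid biomarker indices for nitrogen cycling.

Two qPCR-derived ratio indices summarize which nitrogen-loss guild dominates
a groundwater well: hzsA / (archaeal + bacterial amoA) contrasts anaerobic
against aerobic ammonium oxidation, and nirS / 16S rRNA approximates the
relative proportion of (cd1-type) denitrifiers in the community. Ladderane
fatty-acid methyl esters, lipids unique to anammox bacteria, provide an
orthogonal relative-abundance measure from GC peak areas against a C19:0
internal standard. Trends along an oxygen gradient are tested by Spearman
rank correlation with exact permutation p-values at survey-scale n.

Below-detection measurements are excluded from ratios rather than imputed;
wells whose required markers sit at the detection limit can be dropped from
the correlation explicitly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENE_MARKERS",
    "SpearmanResult",
    "hzsa_amoa_ratio",
    "nirs_16s_ratio",
    "spearman_with_exclusions",
    "ladderane_relative_concentration",
    "well_contrast_factor",
    "LADDERANE_DETECTION_THRESHOLD",
]

GENE_MARKERS = ("16S", "hzsA", "nirS", "nirK", "amoA_AOA", "amoA_AOB")

# relative concentrations below this are reported as below detection
LADDERANE_DETECTION_THRESHOLD = 0.01

EXACT_PERMUTATION_MAX_N = 8  # full n! enumeration up to here
MC_PERMUTATION_MAX_N = 10  # Monte-Carlo permutation up to here, t beyond
_MC_PERMUTATIONS = 100_000
_MC_SEED = 20151101  # fixed: permutation p-values must be reproducible


def _marker_value(
    sub: pd.DataFrame, marker: str, molecule: str
) -> tuple[float | None, bool]:
    """(copies, below_detection) for one marker/molecule, None if absent."""
    rows = sub[(sub["marker"] == marker) & (sub["molecule"] == molecule)]
    if rows.empty:
        return None, False
    row = rows.iloc[0]
    return float(row["copies"]), bool(row["below_detection"])


def hzsa_amoa_ratio(table: pd.DataFrame, molecule: str = "gene") -> pd.DataFrame:
    """Per-well hzsA / (amoA_AOA + amoA_AOB) ratio index.

    High values mark wells where the genetic potential (``molecule`` =
    "gene") or transcriptional activity ("transcript") of anammox
    dominates over aerobic ammonia oxidation. The amoA denominator sums
    only quantified domains; with exactly one domain below detection the
    ratio is computed against the other and flagged ``partial``, with
    both below detection the well is excluded. Below-detection hzsA also
    excludes the well: no imputation is done.
    """
    if molecule not in ("gene", "transcript"):
        raise ValueError("molecule must be 'gene' or 'transcript'")
    out = []
    for well, sub in table.groupby("well", sort=True):
        hzsa, hzsa_bd = _marker_value(sub, "hzsA", molecule)
        if hzsa is None:
            raise ValueError(f"well {well}: no hzsA {molecule} row")
        aoa, aoa_bd = _marker_value(sub, "amoA_AOA", molecule)
        aob, aob_bd = _marker_value(sub, "amoA_AOB", molecule)
        if aoa is None and aob is None:
            raise ValueError(f"well {well}: no amoA {molecule} rows")
        amoa_parts = [
            v
            for v, bd in ((aoa, aoa_bd), (aob, aob_bd))
            if v is not None and not bd
        ]
        n_amoa_present = sum(v is not None for v in (aoa, aob))
        record = {
            "well": well,
            "molecule": molecule,
            "hzsa_amoa": math.nan,
            "excluded": False,
            "partial": False,
            "reason": "",
        }
        if hzsa_bd:
            record.update(excluded=True, reason="hzsA below detection")
        elif not amoa_parts:
            record.update(excluded=True, reason="all amoA below detection")
        else:
            denom = sum(amoa_parts)
            if denom == 0:
                record.update(excluded=True, reason="zero amoA copies")
            else:
                record["hzsa_amoa"] = hzsa / denom
                if len(amoa_parts) < n_amoa_present:
                    record.update(
                        partial=True,
                        reason="one amoA domain below detection; "
                        "ratio uses the quantified domain only",
                    )
        out.append(record)
    return pd.DataFrame(out)


def nirs_16s_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well nirS / 16S rRNA gene copy ratio (denitrifier proportion)."""
    out = []
    for well, sub in table.groupby("well", sort=True):
        nirs, nirs_bd = _marker_value(sub, "nirS", "gene")
        ssu, ssu_bd = _marker_value(sub, "16S", "gene")
        if nirs is None or ssu is None:
            raise ValueError(f"well {well}: need nirS and 16S gene rows")
        record = {
            "well": well,
            "molecule": "gene",
            "nirs_16s": math.nan,
            "excluded": False,
            "reason": "",
        }
        if ssu_bd or ssu == 0:
            record.update(excluded=True, reason="16S denominator unusable")
        elif nirs_bd:
            record.update(excluded=True, reason="nirS below detection")
        else:
            record["nirs_16s"] = nirs / ssu
        out.append(record)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact", "monte-carlo", or "t-approx"
    excluded_wells: tuple[str, ...] = ()
    degenerate: bool = False


def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def spearman_with_exclusions(
    values: pd.Series,
    oxygen: pd.Series,
    exclude: tuple[str, ...] | list[str] = (),
) -> SpearmanResult:
    """Spearman correlation of a per-well index against oxygen.

    Both inputs are indexed by well; wells in ``exclude`` (e.g. those whose
    markers sit at the detection limit) and wells with missing values are
    dropped first. Ties get average ranks. The two-sided p-value is by
    exact enumeration of all n! rank permutations for n <= 8, a seeded
    Monte-Carlo permutation for n = 9-10, and the t approximation beyond
    — survey-scale well counts thus get an exact small-sample test.
    """
    common = values.index.intersection(oxygen.index)
    keep = [w for w in common if w not in set(exclude)]
    x = values.loc[keep].astype(float)
    y = oxygen.loc[keep].astype(float)
    mask = x.notna() & y.notna()
    x, y = x[mask].to_numpy(), y[mask].to_numpy()
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 wells after exclusions, got {n}")
    rx, ry = _rank_average(x), _rank_average(y)
    rho = _rho_of_ranks(rx, ry)
    if math.isnan(rho):
        return SpearmanResult(
            rho=0.0,
            p_value=1.0,
            n=n,
            method="degenerate",
            excluded_wells=tuple(exclude),
            degenerate=True,
        )
    if n <= EXACT_PERMUTATION_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rho_of_ranks(rx, ry[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    elif n <= MC_PERMUTATION_MAX_N:
        rng = np.random.default_rng(_MC_SEED)
        count = 0
        for _ in range(_MC_PERMUTATIONS):
            r = _rho_of_ranks(rx, rng.permutation(ry))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (_MC_PERMUTATIONS + 1)
        method = "monte-carlo"
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
        method = "t-approx"
    return SpearmanResult(
        rho=rho,
        p_value=float(p),
        n=n,
        method=method,
        excluded_wells=tuple(exclude),
    )


def ladderane_relative_concentration(peaks: pd.DataFrame) -> pd.DataFrame:
    """Ladderane relative concentration per well/date from GC peak areas.

    rel = (area of [3]-ladderane FAME + area of [5]-ladderane FAME) /
    area of the C19:0 internal standard. Values below 0.01 are flagged
    below detection. Expects columns ``well``, ``date``,
    ``area_ladderane3``, ``area_ladderane5``, ``area_C19_IS``.
    """
    required = {"well", "date", "area_ladderane3", "area_ladderane5", "area_C19_IS"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peaks[["area_ladderane3", "area_ladderane5", "area_C19_IS"]] < 0).any().any():
        raise ValueError("negative peak areas")
    if (peaks["area_C19_IS"] == 0).any():
        raise ValueError("internal-standard peak area of zero: measurement undefined")
    out = peaks[["well", "date"]].copy()
    out["relative_concentration"] = (
        peaks["area_ladderane3"] + peaks["area_ladderane5"]
    ) / peaks["area_C19_IS"]
    out["below_detection"] = (
        out["relative_concentration"] < LADDERANE_DETECTION_THRESHOLD
    )
    return out


def well_contrast_factor(
    rel: pd.DataFrame, well_a: str, well_b: str
) -> tuple[float, str | None]:
    """Fold difference of mean ladderane relative concentration, a over b.

    Returns ``(factor, flag)``; the factor is NaN with an explanatory flag
    when the denominator well is below detection or zero.
    """
    def _mean(well: str) -> tuple[float, bool]:
        sub = rel[rel["well"] == well]
        if sub.empty:
            raise ValueError(f"well {well} not present in table")
        return (
            float(sub["relative_concentration"].mean()),
            bool(sub["below_detection"].all()),
        )

    val_a, _ = _mean(well_a)
    val_b, bd_b = _mean(well_b)
    if val_b == 0:
        return math.nan, f"denominator well {well_b} has zero relative concentration"
    if bd_b:
        return math.nan, f"denominator well {well_b} is below detection"
    return val_a / val_b, None
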