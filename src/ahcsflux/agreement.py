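"""Method-agreement statistics for paired per-animal flux estimates.

Agreement of a candidate estimator with the gold standard (mean of all
>=3-min visits) is decomposed as in Lin (1989):

* precision — Pearson's correlation coefficient r;
* accuracy — the bias correction factor Cb in (0, 1], penalising location
  and scale shifts;
* agreement — Lin's concordance correlation coefficient CCC = r * Cb,

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2),

with population (divide-by-n) moments, matching Lin's original estimator.
Error magnitude is summarised as RMSE expressed as a percent of the gold
mean.  CCC >= 0.90 is the conventional cut for "excellent agreement".
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: default CCC cut for "excellent agreement"
EXCELLENT_CCC = 0.90


@dataclass(frozen=True)
class AgreementStats:
    """Paired comparison of candidate vs gold-standard estimates."""

    r: float
    cb: float
    ccc: float
    rmse_pct: float
    n_pairs: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation."""
    x, y = _validate_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient and its decomposition.

    Returns ``(r, Cb, ccc)`` with population (1/n) variances and covariance.
    With the squared mean difference in the denominator, the 1/n and
    1/(n-1) conventions give different values, so the convention is pinned
    here.  When r is numerically zero, Cb is returned as NaN (undefined)
    rather than divided out.
    """
    x, y = _validate_pair(x, y)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = np.var(x)  # 1/n
    sy2 = np.var(y)
    sxy = ((x - mx) * (y - my)).sum() / n
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = pearson_r(x, y)
    cb = ccc / r if abs(r) > 1e-12 else float("nan")
    return float(r), float(cb), float(ccc)


def rmse_percent(candidate: np.ndarray, gold: np.ndarray) -> float:
    """Root mean square error of the pairs, as a percent of the gold mean."""
    candidate = np.asarray(candidate, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if candidate.shape != gold.shape:
        raise ValueError("candidate and gold must have equal length")
    gold_mean = gold.mean()
    if gold_mean == 0:
        raise ValueError("gold-standard mean is zero; RMSE%% undefined")
    rmse = float(np.sqrt(np.mean((candidate - gold) ** 2)))
    return 100.0 * rmse / float(gold_mean)


def agreement(candidate: np.ndarray, gold: np.ndarray) -> AgreementStats:
    """Full comparison battery on paired vectors."""
    r, cb, ccc = lin_ccc(candidate, gold)
    return AgreementStats(
        r=r,
        cb=cb,
        ccc=ccc,
        rmse_pct=rmse_percent(candidate, gold),
        n_pairs=len(np.asarray(candidate)),
    )


def compare_estimates(
    candidate: pd.DataFrame, gold: pd.DataFrame
) -> AgreementStats:
    """Compare candidate vs gold per-animal estimate frames.

    Both frames must carry the same gas; animals present on only one side
    are dropped (the intersection is compared and ``n_pairs`` recorded).
    """
    gases_c = set(candidate["gas"].unique())
    gases_g = set(gold["gas"].unique())
    if gases_c != gases_g or len(gases_c) != 1:
        raise ValueError(f"gas mismatch: candidate {gases_c} vs gold {gases_g}")
    merged = candidate.merge(gold, on="animal_id", suffixes=("_cand", "_gold"))
    if len(merged) < 3:
        raise ValueError(f"fewer than 3 pairable animals ({len(merged)})")
    return agreement(
        merged["estimate_cand"].to_numpy(), merged["estimate_gold"].to_numpy()
    )


def ccc_matrix(cand: np.ndarray, gold: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised agreement battery over stacked candidate vectors.

    ``cand`` has shape ``(..., n_pairs)``; ``gold`` has shape ``(n_pairs,)``
    and is broadcast.  Returns arrays ``r``, ``cb``, ``ccc``, ``rmse_pct``
    of shape ``cand.shape[:-1]``.  Used by the subsampling grid, where many
    thousands of cells are evaluated; equals the scalar routines cell by
    cell.
    """
    cand = np.asarray(cand, dtype=float)
    gold = np.asarray(gold, dtype=float)
    n = gold.shape[-1]
    mc = cand.mean(axis=-1)
    mg = gold.mean()
    dc = cand - mc[..., None]
    dg = gold - mg
    sc2 = (dc**2).mean(axis=-1)
    sg2 = (dg**2).mean()
    scg = (dc * dg).mean(axis=-1)
    r = scg / np.sqrt(sc2 * sg2)
    ccc = 2.0 * scg / (sc2 + sg2 + (mc - mg) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cb = np.where(np.abs(r) > 1e-12, ccc / r, np.nan)
    rmse_pct = 100.0 * np.sqrt(((cand - gold) ** 2).mean(axis=-1)) / mg
    return {"r": r, "cb": cb, "ccc": ccc, "rmse_pct": rmse_pct, "n_pairs": n}
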