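"""Per-quadrat diversity: richness, Shannon entropy, Hill evenness, effective species number.

Entropy is in nats throughout.  Adults are weighted by basal area, seedlings
by individual counts; the weighting can be overridden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_PTOL = 1e-9


def basal_area(dbh):
    """Cross-sectional stem area (cm^2) at breast height, (pi/4) * DBH^2.

    Defined for adult stems only (DBH >= 1 cm).
    """
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh < 1.0):
        raise ValueError("basal area is defined for adult stems (DBH >= 1 cm)")
    out = np.pi / 4.0 * dbh ** 2
    return float(out) if out.ndim == 0 else out


def shannon_entropy(p) -> float:
    """H = -sum p_i ln p_i (nats), with 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    s = p.sum()
    if s == 0:
        raise ValueError("all-zero proportion vector")
    if abs(s - 1.0) > _PTOL:
        raise ValueError(f"proportions must sum to 1 (got {s!r})")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def hill_evenness(H: float, S: int) -> float:
    """Hill evenness e^H / S; 1 iff the community is perfectly even."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if H < -_PTOL or H > np.log(S) + 1e-9:
        raise ValueError(f"entropy H={H} outside [0, ln S] for S={S}")
    return float(np.exp(max(H, 0.0)) / S)


def effective_species_number(H: float) -> float:
    """Effective species number e^H: the equally-abundant equivalent richness."""
    if H < 0:
        raise ValueError("entropy must be non-negative")
    return float(np.exp(H))


def diversity_profile(weights) -> dict:
    """Richness, entropy, evenness, and effective species number of one community.

    ``weights`` are non-negative abundances (counts or basal areas); zero-weight
    species are dropped.
    """
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("community has no positive weights")
    p = w / w.sum()
    H = shannon_entropy(p)
    S = int(p.size)
    return {
        "S": S,
        "H": H,
        "evenness": hill_evenness(H, S),
        "diversity": effective_species_number(H),
    }


def quadrat_diversity(census: pd.DataFrame, stage: str,
                      weighting: str | None = None,
                      quadrat_col: str = "quadrat_id") -> pd.DataFrame:
    """Diversity profile of every occupied quadrat in a single-stage census slice.

    Parameters
    ----------
    census : DataFrame
        Stem records of one census and one life stage with at least
        ``quadrat_col``, ``species_id`` and (for adults) ``dbh``.
    stage : {"seedling", "adult"}
        Determines the default weighting: counts for seedlings, basal area
        for adults.
    weighting : {"abundance", "basal_area"}, optional
        Override of the stage default.

    Empty quadrats do not appear in the output (they are missing, not zero).
    """
    if stage not in ("seedling", "adult"):
        raise ValueError("stage must be 'seedling' or 'adult'")
    if "stage" in census.columns and census["stage"].nunique() > 1:
        raise ValueError("census slice mixes life stages")
    weighting = weighting or ("basal_area" if stage == "adult" else "abundance")
    if weighting == "basal_area":
        w = basal_area(census["dbh"].to_numpy())
    elif weighting == "abundance":
        w = np.ones(len(census))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    df = census[[quadrat_col, "species_id"]].copy()
    df["w"] = w
    rows = []
    for qid, grp in df.groupby(quadrat_col, sort=True):
        totals = grp.groupby("species_id")["w"].sum()
        prof = diversity_profile(totals.to_numpy())
        prof[quadrat_col] = qid
        prof["stage"] = stage
        rows.append(prof)
    out = pd.DataFrame(rows)
    return out[[quadrat_col, "stage", "S", "H", "evenness", "diversity"]]
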