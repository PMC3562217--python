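"""Agreement and clinical-contrast statistics.

Bland-Altman method comparison (bias, SD of paired differences, limits of
agreement at bias +/- 2 SD), percent-of-normal strain, remote/infarct
sector classification from late-enhancement transmurality, and paired
observer-difference summaries by basal / mid+apical segment groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "classify_remote",
    "percent_of_normal",
    "observer_difference_summary",
    "AHA17_ADJACENCY",
    "REMOTE",
    "INFARCT",
    "NEITHER",
]

REMOTE = "REMOTE"
INFARCT = "INFARCT"
NEITHER = "NEITHER"


def _build_adjacency() -> dict[int, frozenset[int]]:
    """Edge adjacency of the standard 17-segment bull's-eye.

    Rings are cyclic (basal 1-6, mid 7-12, apical 13-16); basal segment i
    borders mid segment i+6; the 6 mid segments map onto the 4 apical
    segments by angular overlap (13: anterior <- 7, 8, 12; 14: septal <-
    8, 9; 15: inferior <- 9, 10, 11; 16: lateral <- 11, 12); the apex (17)
    borders all four apical segments.
    """
    edges: set[tuple[int, int]] = set()

    def ring(members):
        for a, b in zip(members, members[1:] + members[:1]):
            edges.add((a, b))

    ring(list(range(1, 7)))
    ring(list(range(7, 13)))
    ring(list(range(13, 17)))
    for i in range(1, 7):
        edges.add((i, i + 6))
    for apical, mids in {13: (7, 8, 12), 14: (8, 9), 15: (9, 10, 11), 16: (11, 12)}.items():
        for m in mids:
            edges.add((apical, m))
    for a in (13, 14, 15, 16):
        edges.add((17, a))

    adj: dict[int, set[int]] = {i: set() for i in range(1, 18)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return {k: frozenset(v) for k, v in adj.items()}


AHA17_ADJACENCY: dict[int, frozenset[int]] = _build_adjacency()


@dataclass
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    bias: float  # mean difference a - b
    sd: float  # sample SD of differences (n - 1 denominator)
    loa: tuple[float, float]  # bias -/+ 2 SD
    n: int
    pairs: pd.DataFrame  # columns: mean, diff

    def summary(self) -> str:
        return f"bias {self.bias:.4g} +/- {self.sd:.4g} (LoA {self.loa[0]:.4g}, {self.loa[1]:.4g}; n={self.n})"


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Bland-Altman comparison of two methods.

    Differences are ``a - b``; the limits of agreement use 2 SD (not
    1.96 SD) around the bias.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa=(bias - 2 * sd, bias + 2 * sd),
        n=int(a.size),
        pairs=pd.DataFrame({"mean": (a + b) / 2.0, "diff": d}),
    )


def classify_remote(
    transmurality: dict[int, float],
    adjacency: dict[int, frozenset[int]] | None = None,
    threshold: float = 0.25,
) -> dict[int, str]:
    """Label sectors INFARCT / REMOTE / NEITHER from infarct transmurality.

    A sector with any infarct (transmurality > 0) is INFARCT.  A sector is
    REMOTE when it contains no infarct and the mean transmurality of its
    adjacent sectors does not exceed ``threshold`` (default 25%).
    Everything else is NEITHER.  Sectors without a transmurality value are
    excluded (with a warning); undefined neighbors are left out of the
    neighbor mean.
    """
    adjacency = adjacency or AHA17_ADJACENCY
    labels: dict[int, str] = {}
    for sec in sorted(adjacency):
        if sec not in transmurality:
            log.warning("sector %d has no transmurality value; excluded", sec)
            continue
        own = float(transmurality[sec])
        if not 0.0 <= own <= 1.0:
            raise ValueError(f"transmurality of sector {sec} outside [0, 1]: {own}")
        if own > 0:
            labels[sec] = INFARCT
            continue
        neigh = [float(transmurality[n]) for n in adjacency[sec] if n in transmurality]
        if neigh and np.mean(neigh) <= threshold:
            labels[sec] = REMOTE
        else:
            labels[sec] = NEITHER
    return labels


def percent_of_normal(
    sector_strains: dict[int, float], normal_map: dict[int, float]
) -> dict[int, float]:
    """Strain as a percentage of the per-sector healthy mean.

    ``100 * strain / normal`` with matching sign conventions, so concordant
    shortening gives a positive percentage.  Zero normal values leave the
    sector undefined (NaN, with a warning).
    """
    out: dict[int, float] = {}
    for sec, val in sector_strains.items():
        normal = normal_map.get(sec)
        if normal is None or np.isnan(val):
            out[sec] = np.nan
            continue
        if normal == 0:
            log.warning("normal strain for sector %d is zero; percent undefined", sec)
            out[sec] = np.nan
            continue
        out[sec] = 100.0 * val / normal
    return out


DEFAULT_GROUPS = {
    "all": tuple(range(1, 18)),
    "mid_apical": tuple(range(7, 18)),
    "basal": tuple(range(1, 7)),
}


def observer_difference_summary(
    measurements_a: dict[int, float],
    measurements_b: dict[int, float],
    groups: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Bias +/- SD of per-sector differences between two observers.

    Groups default to all / mid+apical (segments 7-17, the apex counted as
    apical) / basal (1-6).  Unpaired sectors are excluded (logged); empty
    groups are reported as missing (NaN), not zero.
    """
    groups = groups or DEFAULT_GROUPS
    paired = sorted(set(measurements_a) & set(measurements_b))
    dropped = sorted((set(measurements_a) ^ set(measurements_b)))
    if dropped:
        log.info("unpaired sector(s) excluded from observer summary: %s", dropped)
    diffs = {s: float(measurements_a[s]) - float(measurements_b[s]) for s in paired}
    rows = []
    for name, members in groups.items():
        d = np.array([diffs[s] for s in members if s in diffs])
        rows.append(
            {
                "group": name,
                "n": int(d.size),
                "bias": float(d.mean()) if d.size else np.nan,
                "sd": float(d.std(ddof=1)) if d.size > 1 else (0.0 if d.size == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows)
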