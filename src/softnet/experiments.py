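"""Scaled-down simulation runners: effective-reticulation-number survey and
the RF/SRF distribution study on random network pairs."""

from __future__ import annotations

from typing import Iterable, Sequence

from .ccp import ccp_solve
from .distances import enumerate_clusters, rf_distance, srf_distance
from .generator import GenSpec, random_pair_stream
from .network import PhyloNetwork

__all__ = [
    "b_histogram",
    "run_b_survey",
    "run_distance_experiment",
    "summary_stats",
]


def b_histogram(net: PhyloNetwork, clusters=None, force: bool = False) -> dict:
    """Histogram of b(N, B) over the cluster space (or a given cluster list).

    Returns counts and fractions per b value, the number of clusters tested
    and the maximum b (= b(N)).
    """
    if clusters is None:
        clusters = enumerate_clusters(net.X, force=force)
    counts: dict[float, int] = {}
    total = 0
    for B in clusters:
        b = ccp_solve(net, B, want_witness=False).b
        counts[b] = counts.get(b, 0) + 1
        total += 1
    fractions = {b: c / total for b, c in counts.items()}
    return {
        "counts": dict(sorted(counts.items())),
        "fractions": dict(sorted(fractions.items())),
        "n_clusters": total,
        "max_b": max(counts) if counts else 0.0,
    }


def run_b_survey(
    nets: Sequence[PhyloNetwork], clusters=None, force: bool = False
) -> list[dict]:
    """One b-histogram row per network (Fig.-3-style stacked percentages)."""
    rows = []
    for i, net in enumerate(nets):
        h = b_histogram(net, clusters=clusters, force=force)
        h["network"] = i
        h["n_reticulations"] = len(net.reticulations)
        rows.append(h)
    return rows


def summary_stats(values: Iterable[float]) -> dict:
    """Mean, variance, skewness (Fisher's g1), min and max of a sample."""
    xs = [float(v) for v in values]
    n = len(xs)
    if n == 0:
        return {"n": 0}
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    return {
        "n": n,
        "mean": mean,
        "variance": m2,
        "skewness": skew,
        "min": min(xs),
        "max": max(xs),
    }


def run_distance_experiment(
    spec: GenSpec,
    n_pairs: int,
    seed: int,
    shortcut: bool = True,
    chunks: int = 1,
) -> tuple[list[dict], dict]:
    """RF and SRF distances over seeded random pairs, with per-metric summaries."""
    rows = []
    for i, (n1, n2) in enumerate(random_pair_stream(spec, n_pairs, seed)):
        rf = rf_distance(n1, n2)
        srf = srf_distance(n1, n2, shortcut=shortcut, chunks=chunks)
        rows.append({"pair": i, "rf": float(rf.value), "srf": float(srf.value)})
    summary = {
        "rf": summary_stats(r["rf"] for r in rows),
        "srf": summary_stats(r["srf"] for r in rows),
    }
    return rows, summary
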