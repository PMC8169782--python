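"""Hypergeometric over-representation analysis over lipid-class pathways.

Significant lipids are tested for enrichment in a small bundled pathway
map defined over lipid classes (and, for linoleic acid metabolism, over
explicitly chain-annotated 18:2 acyls).  The background is the set of
annotated lipids in the analyzed table, per standard ORA practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .lipids import parse_name

__all__ = [
    "PathwayDefinition",
    "EnrichmentResult",
    "DEFAULT_PATHWAYS",
    "hypergeometric_p",
    "enrich",
]


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    member: Callable[[str], bool]  # predicate over lipid names


def _class_of(name: str) -> str | None:
    try:
        return parse_name(name)[0]
    except ValueError:
        return None


def _class_member(classes: frozenset) -> Callable[[str], bool]:
    return lambda name: _class_of(name) in classes


def _has_linoleoyl(name: str) -> bool:
    """True for chain-annotated names containing an 18:2 acyl.

    Sum-composition names cannot resolve individual chains and are
    never members.
    """
    if _class_of(name) is None:
        return False
    body = name.split(None, 1)[1]
    chains = body.replace("/", "_").split("_")
    if len(chains) < 2 and _class_of(name) not in ("LPC", "FA", "CE"):
        return False  # sum composition of a multi-chain class
    # a leading 'd' marks the sphingoid base, which is not an acyl chain
    return any(not ch.startswith("d") and ch.lstrip("O-") == "18:2"
               for ch in chains)


DEFAULT_PATHWAYS: tuple[PathwayDefinition, ...] = (
    PathwayDefinition("glycerophospholipid metabolism",
                      _class_member(frozenset({"PC", "LPC", "PE", "PS", "PA"}))),
    PathwayDefinition("sphingolipid metabolism",
                      _class_member(frozenset({"SM", "Cer"}))),
    PathwayDefinition("ether lipid metabolism",
                      _class_member(frozenset({"PC-O", "PE-O"}))),
    PathwayDefinition("glycerolipid metabolism",
                      _class_member(frozenset({"TG"}))),
    PathwayDefinition("linoleic acid metabolism", _has_linoleoyl),
)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int  # significant lipids in pathway
    K: int  # background lipids in pathway
    n: int  # significant lipids
    N: int  # background lipids
    p: float
    p_adj_bh: float = float("nan")


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(_st.hypergeom.sf(k - 1, N, K, n))


def enrich(
    significant: Iterable[str],
    background: Iterable[str],
    pathways: tuple[PathwayDefinition, ...] = DEFAULT_PATHWAYS,
) -> list[EnrichmentResult]:
    """ORA of a significant lipid set against the annotated background.

    One result per pathway with non-empty background membership, sorted
    by ascending p; BH adjustment across the tested pathways.
    """
    sig = sorted(set(significant))
    bg = sorted(set(background))
    if not bg:
        raise ValueError("background must be non-empty")
    offenders = [s for s in sig if s not in set(bg)]
    if offenders:
        raise ValueError(f"significant lipids missing from background: {offenders}")
    results = []
    for pw in pathways:
        members_bg = [b for b in bg if pw.member(b)]
        if not members_bg:
            continue
        member_set = set(members_bg)
        k = sum(1 for s in sig if s in member_set)
        res = EnrichmentResult(
            pathway=pw.name, k=k, K=len(members_bg), n=len(sig), N=len(bg),
            p=hypergeometric_p(k, len(members_bg), len(sig), len(bg)),
        )
        results.append(res)
    if results:
        adj = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.pathway, r.k, r.K, r.n, r.N, r.p, float(a))
            for r, a in zip(results, adj)
        ]
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj_BH": [r.p_adj_bh for r in results],
        }
    )
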