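"""Nine-feature evidence assembly for candidate protein pairs.

Each candidate pair gets a boolean vector over nine evidence sources:
human physical PPIs, interologs projected from fly/worm/yeast, a
domain-domain interaction, two co-expression sets, shared GO
biological-process annotation, and text-mined PPIs.  Evidence is assembled
under a closed-world assumption — absence of a record means ``False``.

Sources are screened for relevance by an odds-ratio analysis against a
reference FI set, with control groups of random pairs drawn from the
reference protein universe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._sampling import sample_pairs

__all__ = [
    "FEATURES",
    "GO_BP_ROOT",
    "OddsRatioResult",
    "load_interactions",
    "expand_record",
    "project_interologs",
    "filter_go_terms",
    "build_feature_matrix",
    "odds_ratio",
]

#: Canonical feature order; columns of every feature matrix.
FEATURES = (
    "human_ppi",
    "fly_interolog",
    "worm_interolog",
    "yeast_interolog",
    "domain_interaction",
    "coexpr_set1",
    "coexpr_set2",
    "go_bp_shared",
    "textmined_ppi",
)

GO_BP_ROOT = "GO:0008150"

Pair = Tuple[str, str]


def _norm(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def expand_record(
    participants: Set[str], max_interactors: int = 4
) -> Set[Pair]:
    """Matrix-expand one interaction record into unordered pairs.

    Records with more than ``max_interactors`` distinct participants are
    dropped entirely (mass-spec pulldown records with many interactors
    correlate poorly with true functional interactions); self-pairs are
    removed.
    """
    distinct = sorted(participants)
    if len(distinct) > max_interactors:
        return set()
    return {_norm(a, b) for a, b in itertools.combinations(distinct, 2)}


def load_interactions(path, max_interactors: int = 4) -> Set[Pair]:
    """Read an evidence file (PSI-MI TAB subset or TSV) into unordered pairs.

    Applies the interactor-count filter and matrix expansion per record.
    """
    from .io import read_evidence_records

    pairs: Set[Pair] = set()
    for record in read_evidence_records(path):
        pairs |= expand_record(record, max_interactors)
    return pairs


def project_interologs(
    pairs: Iterable[Pair], ortholog_map: Dict[str, Set[str]]
) -> Set[Pair]:
    """Project non-human interaction pairs onto human pairs via orthology.

    For a pair (x, y) every human pair (hx, hy) with hx in map[x] and
    hy in map[y], hx != hy, is emitted.  Unmapped proteins contribute
    nothing.
    """
    out: Set[Pair] = set()
    for x, y in pairs:
        for hx in ortholog_map.get(x, ()):
            for hy in ortholog_map.get(y, ()):
                if hx != hy:
                    out.add(_norm(hx, hy))
    return out


def filter_go_terms(
    annotations: Dict[str, Set[str]],
    max_fraction: float = 0.25,
    roots: Iterable[str] = (GO_BP_ROOT,),
) -> Dict[str, Set[str]]:
    """Drop root and overly broad terms from an annotation table.

    A term annotating at least ``max_fraction`` of the annotated proteins
    is considered too broad to signal a specific shared process.
    """
    roots = set(roots)
    n_annotated = len(annotations)
    counts: Dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    keep = {
        t
        for t, c in counts.items()
        if t not in roots and (n_annotated == 0 or c / n_annotated < max_fraction)
    }
    return {
        p: terms & keep for p, terms in annotations.items() if terms & keep
    }


def build_feature_matrix(
    candidates: Iterable[Pair],
    pair_sources: Dict[str, Set[Pair]],
    go_bp: Optional[Dict[str, Set[str]]] = None,
    domain_map: Optional[Dict[str, Set[str]]] = None,
    domain_pairs: Optional[Set[Pair]] = None,
    go_max_fraction: float = 0.25,
) -> pd.DataFrame:
    """Boolean feature matrix (pairs x nine features).

    ``pair_sources`` maps feature names to human pair sets (interolog
    sources must already be projected).  ``go_bp`` is a raw biological-
    process annotation table, breadth-filtered here; ``domain_map`` and
    ``domain_pairs`` drive the domain-interaction feature.  Features
    without a supplied source are all-``False`` (closed world).
    """
    unknown = set(pair_sources) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown feature sources: {sorted(unknown)}")
    cands = sorted({_norm(a, b) for a, b in candidates})
    for a, b in cands:
        if a == b:
            raise ValueError(f"candidate self-pair {a!r}")

    filtered_go = (
        filter_go_terms(go_bp, max_fraction=go_max_fraction)
        if go_bp is not None
        else {}
    )
    dmap = domain_map or {}
    dpairs = domain_pairs or set()

    data = {}
    for feat in FEATURES:
        if feat == "go_bp_shared" and go_bp is not None:
            col = [
                bool(
                    filtered_go.get(a, set()) & filtered_go.get(b, set())
                )
                for a, b in cands
            ]
        elif feat == "domain_interaction" and domain_pairs is not None:
            col = [
                any(
                    _norm(da, db) in dpairs
                    for da in dmap.get(a, ())
                    for db in dmap.get(b, ())
                )
                for a, b in cands
            ]
        else:
            src = pair_sources.get(feat, set())
            col = [p in src for p in cands]
        data[feat] = col
    index = pd.MultiIndex.from_tuples(cands, names=["proteinA", "proteinB"])
    return pd.DataFrame(data, index=index, dtype=bool)


@dataclass(frozen=True)
class OddsRatioResult:
    """Mean +- sd odds ratio of a source against a reference FI set."""

    odds_ratio: float
    sd: float
    n_permutations: int


def odds_ratio_from_counts(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with Haldane-Anscombe +0.5 applied when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def odds_ratio(
    feature_pairs: Set[Pair],
    reference_fis: Set[Pair],
    universe: Sequence[str],
    n_perm: int = 10,
    seed: Optional[int] = None,
) -> OddsRatioResult:
    """Odds ratio of a pairwise evidence source against reference FIs.

    For each permutation an equal-size control group of random pairs is
    drawn from the reference protein universe; the 2x2 table crosses
    membership in the evidence source with reference-vs-control origin.
    """
    universe = sorted(set(universe))
    upairs_allowed = set(universe)
    feats = {
        p
        for p in feature_pairs
        if p[0] in upairs_allowed and p[1] in upairs_allowed
    }
    n_draw = len(feats)
    if n_draw == 0:
        raise ValueError("no evidence pairs fall inside the universe")
    rng = np.random.default_rng(seed)
    a = len(feats & reference_fis)
    c = len(reference_fis - feats)
    ors = []
    for _ in range(n_perm):
        control = sample_pairs(universe, n_draw, rng)
        b = len(feats & control)
        d = n_draw - b
        ors.append(odds_ratio_from_counts(a, b, c, d))
    ors = np.asarray(ors)
    return OddsRatioResult(
        odds_ratio=float(ors.mean()),
        sd=float(ors.std(ddof=1)) if n_perm > 1 else 0.0,
        n_permutations=n_perm,
    )
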