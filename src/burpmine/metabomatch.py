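"""Matching predicted compounds to LC-MS features and spectral networking.

Two complementary links connect the transcriptome predictions to the
metabolome: (1) exact-mass matching of predicted adduct m/z values to
LC-MS features within a ppm tolerance, and (2) a GNPS-style molecular
network in which MS/MS spectra are connected by the modified cosine
score — a normalised dot product that pairs fragments either directly or
offset by the difference of the two precursor masses, so that related
(modified) compounds with shifted fragment series still align.  The
network defaults mirror the GNPS parameters used for the plant extracts:
0.2 Da precursor tolerance, 0.5 Da fragment tolerance, and a minimum of
8 matched fragment ions per edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .burpchem import CompoundPrediction
from .seqformats import MsFeature, Spectrum

__all__ = [
    "NetworkParams", "MatchResult", "NetworkEdge",
    "match_features", "modified_cosine", "build_network",
    "consensus_groups", "connected_components",
]


@dataclass
class NetworkParams:
    """Molecular-networking parameters (defaults as used for the plant
    extract networks: 0.2 Da / 0.5 Da / 8 matched ions)."""

    precursor_tol: float = 0.2      # Da
    fragment_tol: float = 0.5       # Da
    min_matched_peaks: int = 8
    score_threshold: float = 0.7    # cosine cutoff (unpinned upstream)

    def __post_init__(self):
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")


@dataclass
class MatchResult:
    """A feature/prediction pair within tolerance."""

    feature_id: str
    prediction: CompoundPrediction
    adduct: str
    ppm_error: float
    n_fragments_matched: int | None = None


def match_features(predictions: Sequence[CompoundPrediction],
                   features: Sequence[MsFeature],
                   ppm_tol: float = 5.0,
                   adducts: Sequence[str] = ("M+H",)) -> list[MatchResult]:
    """All (feature, prediction, adduct) pairs within ppm tolerance.

    ppm_error = (observed - predicted) / predicted * 1e6; results are
    sorted by absolute ppm error.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not predictions or not features:
        raise ValueError("need non-empty predictions and features")
    out: list[MatchResult] = []
    for feat in features:
        for pred in predictions:
            for adduct in adducts:
                mz = pred.adduct_mz.get(adduct)
                if mz is None:
                    continue
                ppm = (feat.mz - mz) / mz * 1e6
                if abs(ppm) <= ppm_tol:
                    out.append(MatchResult(feature_id=feat.feature_id,
                                           prediction=pred, adduct=adduct,
                                           ppm_error=ppm))
    out.sort(key=lambda m: (abs(m.ppm_error), m.feature_id))
    return out


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tol: float = 0.5,
                    allow_shift: bool = True) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Peaks pair either directly (|dmz| <= tol) or offset by the precursor
    mass difference (when ``allow_shift``).  Pairs are selected greedily
    by descending sqrt-intensity product with each peak used once; the
    score is normalised so identical spectra give 1.0.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("empty spectrum")
    shift = a.precursor_mz - b.precursor_mz
    amz = np.array([p[0] for p in a.peaks])
    ain = np.sqrt(np.array([p[1] for p in a.peaks]))
    bmz = np.array([p[0] for p in b.peaks])
    bin_ = np.sqrt(np.array([p[1] for p in b.peaks]))

    pairs: dict[tuple[int, int], float] = {}
    d = np.abs(amz[:, None] - bmz[None, :])
    for i, j in zip(*np.nonzero(d <= fragment_tol)):
        pairs[(int(i), int(j))] = float(ain[i] * bin_[j])
    if allow_shift and abs(shift) > fragment_tol:
        ds = np.abs(amz[:, None] - bmz[None, :] - shift)
        for i, j in zip(*np.nonzero(ds <= fragment_tol)):
            key = (int(i), int(j))
            w = float(ain[i] * bin_[j])
            if key not in pairs or w > pairs[key]:
                pairs[key] = w

    order = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    n_matched = 0
    for (i, j), w in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += w
        n_matched += 1
    norm = math.sqrt(float(np.sum(ain ** 2)) * float(np.sum(bin_ ** 2)))
    score = total / norm if norm > 0 else 0.0
    return min(score, 1.0), n_matched


@dataclass
class NetworkEdge:
    id_a: str
    id_b: str
    score: float
    n_matched: int


def consensus_groups(spectra: Sequence[Spectrum],
                     precursor_tol: float = 0.2) -> list[list[Spectrum]]:
    """Single-linkage grouping of spectra by precursor m/z.

    Mirrors the clustering intent of GNPS consensus nodes with a
    deterministic rule: spectra whose precursors are within the
    tolerance of any group member join that group.
    """
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.spectrum_id))
    groups: list[list[Spectrum]] = []
    for sp in ordered:
        if groups and sp.precursor_mz - groups[-1][-1].precursor_mz \
                <= precursor_tol:
            groups[-1].append(sp)
        else:
            groups.append([sp])
    return groups


def build_network(spectra: Sequence[Spectrum],
                  params: NetworkParams | None = None) -> list[NetworkEdge]:
    """Pairwise modified-cosine network over a spectrum set.

    An edge exists iff score >= score_threshold and matched peaks >=
    min_matched_peaks; no self-edges.  Edges are returned sorted by
    descending score (ties by ids).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    params = params or NetworkParams()
    edges: list[NetworkEdge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, nm = modified_cosine(spectra[i], spectra[j],
                                        fragment_tol=params.fragment_tol)
            if score >= params.score_threshold and \
                    nm >= params.min_matched_peaks:
                edges.append(NetworkEdge(spectra[i].spectrum_id,
                                         spectra[j].spectrum_id,
                                         score, nm))
    edges.sort(key=lambda e: (-e.score, e.id_a, e.id_b))
    return edges


def connected_components(edges: Sequence[NetworkEdge]) -> list[set[str]]:
    """Connected components of an edge list (singletons not included)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.id_a, e.id_b)
    return [set(c) for c in nx.connected_components(g)]
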