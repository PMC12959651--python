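"""Feature engineering for deletion variants.

Four feature categories are produced:

``context``
    Sequence-logo bit-score sums over the five residues flanking the
    deletion on each side, computed separately against a benign-trained and
    a pathogenic-trained logo, plus their summed difference.
``content``
    Averages over the deleted residues: physicochemical propensity scales
    and provider-supplied per-residue tracks (conservation, solvent
    accessibility, substitution-pathogenicity score).
``position``
    Deletion length, relative position, distance to the nearer terminus,
    and binary overlap flags against annotation tracks (domains, repeats,
    transmembrane segments, disordered regions, palindromes, secondary
    structure, ...).
``gene``
    Gene/protein-level values: classification flags, interaction-network
    centralities, gene age.

Logos must be built on training variants only; the
:class:`FeatureExtractor` records this by being a fit/transform estimator —
``fit`` consumes training variants, ``transform`` may then be applied to any
variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from delpath.io import (
    AMINO_ACIDS,
    AnnotationTrack,
    DeletionVariant,
    NumericAnnotation,
    PropertyScale,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

PAD = "X"
SEGMENT_LEN = 5
MAX_INFO_BITS = math.log2(20)

#: flank offsets relative to the deletion: -5..-1 upstream, +1..+5 downstream
UPSTREAM_OFFSETS = tuple(range(-5, 0))
DOWNSTREAM_OFFSETS = tuple(range(1, 6))


# ---------------------------------------------------------------------------
# position logos and context bit scores


@dataclass
class PositionLogo:
    """Per-offset residue frequencies and information content (bits).

    ``freqs[offset]`` maps amino acid → frequency (summing to 1);
    ``info[offset]`` = log2(20) − Shannon entropy of that column, in
    [0, log2 20].  The bit score of letter *a* at an offset is
    ``freqs[offset][a] * info[offset]``.
    """

    class_tag: str
    freqs: dict[int, dict[str, float]] = field(default_factory=dict)
    info: dict[int, float] = field(default_factory=dict)

    def bit_score(self, residue: str, offset: int) -> float:
        """Frequency × information content; 0 for unseen residues/offsets."""
        col = self.freqs.get(offset)
        if not col:
            return 0.0
        return col.get(residue, 0.0) * self.info.get(offset, 0.0)


def _flank_residue(protein: ProteinRecord, variant: DeletionVariant, offset: int) -> str | None:
    """Residue at a flank offset, or None beyond the protein terminus."""
    if offset < 0:
        pos = variant.start + offset  # offset -1 = residue just before start
    else:
        pos = variant.end + offset
    if 1 <= pos <= protein.length:
        return protein.sequence[pos - 1]
    return None


def build_position_logo(
    variants: Sequence[DeletionVariant],
    proteins: Mapping[str, ProteinRecord],
    class_tag: str,
) -> PositionLogo:
    """Build a flank logo from all variants of one class.

    Windows clipped at protein termini contribute only their existing
    positions.  An offset with zero observations gets uniform frequencies
    and information content 0.
    """
    if not variants:
        raise ValueError("cannot build a logo from zero variants")
    logo = PositionLogo(class_tag=class_tag)
    for offset in UPSTREAM_OFFSETS + DOWNSTREAM_OFFSETS:
        counts: dict[str, int] = {}
        for v in variants:
            protein = proteins[v.protein_id]
            res = _flank_residue(protein, v, offset)
            if res is not None and res in AMINO_ACIDS:
                counts[res] = counts.get(res, 0) + 1
        total = sum(counts.values())
        if total == 0:
            logger.info("logo %s: no observations at offset %+d", class_tag, offset)
            logo.freqs[offset] = {a: 1.0 / 20 for a in AMINO_ACIDS}
            logo.info[offset] = 0.0
            continue
        freqs = {a: c / total for a, c in counts.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        logo.freqs[offset] = freqs
        logo.info[offset] = max(0.0, MAX_INFO_BITS - entropy)
    return logo


def context_bitscores(
    variant: DeletionVariant,
    protein: ProteinRecord,
    logos: Mapping[str, PositionLogo],
) -> dict[str, float]:
    """Summed flank bit scores against each class logo.

    For each logo (keyed ``benign`` / ``pathogenic``) the observed residues
    at the ≤5 upstream offsets are scored and summed, likewise downstream.
    Positions beyond a terminus contribute 0.  Returns the four sums plus
    their overall pathogenic-minus-benign difference.
    """
    sums: dict[str, float] = {}
    for tag, logo in logos.items():
        for side, offsets in (("up", UPSTREAM_OFFSETS), ("down", DOWNSTREAM_OFFSETS)):
            total = 0.0
            for offset in offsets:
                res = _flank_residue(protein, variant, offset)
                if res is not None:
                    total += logo.bit_score(res, offset)
            sums[f"ctx_{side}_{tag}"] = total
    sums["ctx_diff"] = (
        sums.get("ctx_up_pathogenic", 0.0)
        + sums.get("ctx_down_pathogenic", 0.0)
        - sums.get("ctx_up_benign", 0.0)
        - sums.get("ctx_down_benign", 0.0)
    )
    return sums


# ---------------------------------------------------------------------------
# segments


@dataclass(frozen=True)
class SegmentTriple:
    """Fixed-width (5-residue) deletion / upstream / downstream segments.

    Shorter stretches are padded with ``X``: upstream on its N-terminal
    (distal) side, downstream on its C-terminal side, the deletion segment
    trimmed to its first five residues and right-padded.  These strings feed
    sequence-encoding models and are excluded from tabular learners.
    """

    deletion_seg: str
    upstream_seg: str
    downstream_seg: str

    def __post_init__(self) -> None:
        for seg in (self.deletion_seg, self.upstream_seg, self.downstream_seg):
            if len(seg) != SEGMENT_LEN:
                raise ValueError(f"segment {seg!r} is not length {SEGMENT_LEN}")


def extract_segments(
    variant: DeletionVariant, protein: ProteinRecord, pad_len: int = SEGMENT_LEN
) -> SegmentTriple:
    seq = protein.sequence
    up = seq[max(0, variant.start - 1 - pad_len) : variant.start - 1]
    down = seq[variant.end : variant.end + pad_len]
    deleted = seq[variant.start - 1 : variant.end][:pad_len]
    return SegmentTriple(
        deletion_seg=deleted.ljust(pad_len, PAD),
        upstream_seg=up.rjust(pad_len, PAD),
        downstream_seg=down.ljust(pad_len, PAD),
    )


# ---------------------------------------------------------------------------
# content averages


def content_average(
    variant: DeletionVariant, protein: ProteinRecord, scale: PropertyScale
) -> float | None:
    """Mean scale value over the deleted residues.

    Non-standard residues (X) are excluded from both numerator and
    denominator; if every deleted residue is non-standard the feature is
    unavailable (None).
    """
    deleted = protein.sequence[variant.start - 1 : variant.end]
    values = [scale.values[a] for a in deleted if a in scale.values]
    if not values:
        return None
    return float(np.mean(values))


def residue_average(
    variant: DeletionVariant, values: np.ndarray
) -> float:
    """Mean of a per-residue annotation vector over the deleted positions."""
    return float(np.mean(values[variant.start - 1 : variant.end]))


# ---------------------------------------------------------------------------
# position features


def position_features(variant: DeletionVariant, protein: ProteinRecord) -> dict[str, float]:
    """Deletion length, relative midpoint position, and terminal distance.

    ``relative_position`` is the deletion midpoint divided by protein
    length; ``distance_to_terminus`` is min(start − 1, L − end).
    """
    length = variant.length
    midpoint = (variant.start + variant.end) / 2.0
    return {
        "pos_length": float(length),
        "pos_relative": midpoint / protein.length,
        "pos_term_distance": float(min(variant.start - 1, protein.length - variant.end)),
        "pos_protein_length": float(protein.length),
    }


def overlap_flags(
    variant: DeletionVariant,
    tracks: Iterable[AnnotationTrack],
    categories: Sequence[str] | None = None,
) -> dict[str, int]:
    """Binary overlap of the deletion with each annotation category.

    The flag is 1 iff the closed interval [start, end] intersects any
    interval of that category for the variant's protein; adjacency is not
    overlap.  When *categories* is given, every listed category gets a flag
    (0 when absent).
    """
    flags: dict[str, int] = {c: 0 for c in categories} if categories else {}
    for track in tracks:
        if track.protein_id != variant.protein_id:
            continue
        if categories is not None and track.category not in flags:
            continue
        if track.overlaps(variant.start, variant.end):
            flags[track.category] = 1
        else:
            flags.setdefault(track.category, 0)
    return flags


# ---------------------------------------------------------------------------
# palindromes


def find_palindromes(sequence: str, min_len: int = 5) -> set[tuple[int, int]]:
    """Maximal palindromic substrings of length ≥ *min_len*.

    A substring is palindromic when it reads identically in both
    directions.  Each reported 1-based closed interval is maximal: it is not
    contained in any other reported interval.  Expansion around each of the
    2n−1 centres gives the longest palindrome per centre in O(n²).
    """
    if min_len < 2:
        raise ValueError("min_len must be ≥ 2")
    n = len(sequence)
    found: list[tuple[int, int]] = []
    for centre in range(2 * n - 1):
        lo, hi = centre // 2, (centre + 1) // 2
        while lo >= 0 and hi < n and sequence[lo] == sequence[hi]:
            lo -= 1
            hi += 1
        lo, hi = lo + 1, hi - 1  # last valid expansion
        if hi - lo + 1 >= min_len:
            found.append((lo + 1, hi + 1))
    # drop intervals nested inside another palindromic interval
    maximal = {
        (s, e)
        for s, e in found
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in found)
    }
    return maximal


def palindrome_track(protein: ProteinRecord, min_len: int = 5) -> AnnotationTrack:
    """Palindromic regions of a protein as an annotation track."""
    intervals = sorted(find_palindromes(protein.sequence, min_len))
    return AnnotationTrack(protein.id, "palindrome", intervals)


# ---------------------------------------------------------------------------
# interaction-network centralities

CENTRALITY_NAMES = (
    "degree",
    "closeness",
    "betweenness",
    "harmonic",
    "hub_score",
    "power",
)


def network_centralities(
    edges: Iterable[tuple[str, str, float]],
    attenuation_scale: float = 0.9,
) -> dict[str, dict[str, float]]:
    """Six per-node centralities of an undirected weighted interaction graph.

    Returns node → {degree, closeness, betweenness, harmonic, hub_score,
    power}.  Closeness uses the component-restricted normalised form;
    betweenness is the raw pair count; harmonic centrality sums reciprocal
    distances; the hub score is the principal eigenvector of the (weighted)
    adjacency matrix scaled to a maximum of 1; power centrality is the
    Bonacich measure with attenuation ``attenuation_scale / λ_max`` and the
    conventional √n scaling.  Isolated nodes get 0 for the distance-based
    measures.
    """
    graph = nx.Graph()
    for u, v, w in edges:
        graph.add_edge(u, v, weight=float(w))
    if graph.number_of_nodes() == 0:
        return {}
    nodes = sorted(graph.nodes())
    degree = dict(graph.degree())
    closeness = nx.closeness_centrality(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    harmonic = nx.harmonic_centrality(graph)

    adjacency = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    eigvals, eigvecs = np.linalg.eigh(adjacency)
    principal = np.abs(eigvecs[:, np.argmax(eigvals)])
    if principal.max() > 0:
        principal = principal / principal.max()
    lam_max = float(np.max(eigvals))

    n = len(nodes)
    if lam_max > 0:
        beta = attenuation_scale / lam_max
        power_raw = np.linalg.solve(
            np.eye(n) - beta * adjacency, adjacency @ np.ones(n)
        )
        norm = np.linalg.norm(power_raw)
        power = power_raw * (math.sqrt(n) / norm) if norm > 0 else power_raw
    else:
        power = np.zeros(n)

    out: dict[str, dict[str, float]] = {}
    for i, node in enumerate(nodes):
        out[node] = {
            "degree": float(degree[node]),
            "closeness": float(closeness[node]),
            "betweenness": float(betweenness[node]),
            "harmonic": float(harmonic[node]),
            "hub_score": float(principal[i]),
            "power": float(power[i]),
        }
    return out


# ---------------------------------------------------------------------------
# providers


class AnnotationProvider:
    """Supplies externally computed per-variant or per-protein features.

    Implementations must be deterministic for fixed inputs and must report
    availability per protein so that variants on proteins with incomplete
    annotation can be excluded with a "prediction not possible" note.
    """

    def available(self, protein_id: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def features(
        self, variant: DeletionVariant, protein: ProteinRecord
    ) -> dict[str, float]:  # pragma: no cover - interface
        raise NotImplementedError

    def feature_names(self) -> list[str]:  # pragma: no cover - interface
        raise NotImplementedError

    def category(self) -> str:
        return "content"


class ResidueTrackProvider(AnnotationProvider):
    """Per-residue numeric tracks averaged over the deleted stretch.

    Typical tracks: conservation information content, solvent accessibility,
    mean substitution-pathogenicity score.
    """

    def __init__(self, name: str, annotations: Iterable[NumericAnnotation]):
        self.name = name
        self._tracks = {
            a.protein_id: np.asarray(a.values, dtype=float)
            for a in annotations
            if a.name == name
        }

    def available(self, protein_id: str) -> bool:
        return protein_id in self._tracks

    def features(self, variant: DeletionVariant, protein: ProteinRecord) -> dict[str, float]:
        values = self._tracks[variant.protein_id]
        return {f"content_{self.name}": residue_average(variant, values)}

    def feature_names(self) -> list[str]:
        return [f"content_{self.name}"]


class ProteinScalarProvider(AnnotationProvider):
    """Per-protein scalars (gene age, gene-class flags, centralities)."""

    def __init__(
        self,
        values: Mapping[str, Mapping[str, float]],
        category: str = "gene",
        prefix: str = "gene_",
    ):
        # values: protein_id -> {name: value}; all proteins share the name set
        self._values = {pid: dict(v) for pid, v in values.items()}
        self._category = category
        self._prefix = prefix
        names: set[str] = set()
        for v in self._values.values():
            names.update(v)
        self._names = sorted(names)

    def available(self, protein_id: str) -> bool:
        v = self._values.get(protein_id)
        return v is not None and all(name in v for name in self._names)

    def features(self, variant: DeletionVariant, protein: ProteinRecord) -> dict[str, float]:
        vals = self._values[variant.protein_id]
        return {self._prefix + name: float(vals[name]) for name in self._names}

    def feature_names(self) -> list[str]:
        return [self._prefix + name for name in self._names]

    def category(self) -> str:
        return self._category


# ---------------------------------------------------------------------------
# feature table assembly

CATEGORY_ORDER = ("context", "content", "position", "gene")


@dataclass
class FeatureTable:
    """Variants × features with a category registry.

    ``data`` holds numeric/binary feature columns plus a ``label`` column,
    indexed by variant id.  ``categories`` maps feature name → category tag
    and ``kinds`` maps feature name → ``numeric`` | ``binary``.  The three
    fixed-width sequence segments live in ``segments`` — registered but kept
    out of tabular-learner input.  ``excluded`` lists variant ids dropped
    because a provider feature was unavailable ("prediction not possible").
    """

    data: pd.DataFrame
    categories: dict[str, str]
    kinds: dict[str, str]
    segments: pd.DataFrame | None = None
    excluded: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "label"]

    def registry_order(self) -> list[str]:
        """Feature names in the canonical category-then-name order."""
        rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
        return sorted(
            self.feature_names,
            key=lambda name: (rank.get(self.categories.get(name, ""), 99), name),
        )

    def binary_columns(self) -> list[str]:
        return [c for c in self.feature_names if self.kinds.get(c) == "binary"]

    def numeric_columns(self) -> list[str]:
        return [c for c in self.feature_names if self.kinds.get(c) == "numeric"]


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Assemble the full feature table for deletion variants.

    The estimator follows fit/transform semantics so that the class logos —
    the only component learnt from labelled data — are always built on the
    training variants passed to :meth:`fit` and never on the variants being
    transformed.

    Parameters
    ----------
    proteins:
        id → :class:`~delpath.io.ProteinRecord` map.
    scales:
        Physicochemical property scales for content averages.
    tracks:
        Annotation-interval tracks for overlap flags.
    providers:
        :class:`AnnotationProvider` instances for external numbers.
    track_categories:
        Explicit category list for overlap flags; inferred from *tracks*
        when omitted.
    include_diff_feature:
        Emit the fifth context feature (pathogenic − benign summed
        difference) alongside the four class-specific sums.
    add_palindrome_track:
        Compute a palindrome track per protein and add its overlap flag.
    palindrome_min_len:
        Minimum palindrome length in residues.
    """

    def __init__(
        self,
        proteins: Mapping[str, ProteinRecord],
        scales: Sequence[PropertyScale] = (),
        tracks: Sequence[AnnotationTrack] = (),
        providers: Sequence[AnnotationProvider] = (),
        track_categories: Sequence[str] | None = None,
        include_diff_feature: bool = True,
        add_palindrome_track: bool = True,
        palindrome_min_len: int = 5,
    ):
        self.proteins = proteins
        self.scales = scales
        self.tracks = tracks
        self.providers = providers
        self.track_categories = track_categories
        self.include_diff_feature = include_diff_feature
        self.add_palindrome_track = add_palindrome_track
        self.palindrome_min_len = palindrome_min_len

    def fit(self, variants: Sequence[DeletionVariant], y=None) -> "FeatureExtractor":
        """Build benign and pathogenic flank logos from training variants."""
        benign = [v for v in variants if v.label == "benign"]
        pathogenic = [v for v in variants if v.label == "pathogenic"]
        if not benign or not pathogenic:
            raise ValueError("fit requires variants of both classes to build logos")
        self.logos_ = {
            "benign": build_position_logo(benign, self.proteins, "benign"),
            "pathogenic": build_position_logo(pathogenic, self.proteins, "pathogenic"),
        }
        self.tracks_ = list(self.tracks)
        if self.add_palindrome_track:
            seen = {t.protein_id for t in self.tracks_ if t.category == "palindrome"}
            for pid, protein in self.proteins.items():
                if pid not in seen:
                    self.tracks_.append(
                        palindrome_track(protein, self.palindrome_min_len)
                    )
        if self.track_categories is not None:
            self.track_categories_ = list(self.track_categories)
        else:
            self.track_categories_ = sorted({t.category for t in self.tracks_})
        return self

    def transform(self, variants: Sequence[DeletionVariant]) -> FeatureTable:
        """Compute the feature table; rows with unavailable features are dropped.

        Dropped variant ids are listed in ``FeatureTable.excluded`` — the
        library-level equivalent of a "prediction not possible" note.
        """
        if not hasattr(self, "logos_"):
            raise RuntimeError("FeatureExtractor must be fit before transform")
        tracks_by_protein: dict[str, list[AnnotationTrack]] = {}
        for t in self.tracks_:
            tracks_by_protein.setdefault(t.protein_id, []).append(t)

        rows: list[dict[str, float]] = []
        labels: list[str] = []
        index: list[str] = []
        seg_rows: list[dict[str, str]] = []
        excluded: list[str] = []
        categories: dict[str, str] = {}
        kinds: dict[str, str] = {}

        for v in variants:
            protein = self.proteins.get(v.protein_id)
            if protein is None:
                excluded.append(v.variant_id)
                continue
            if not all(p.available(v.protein_id) for p in self.providers):
                excluded.append(v.variant_id)
                continue
            row: dict[str, float] = {}

            ctx = context_bitscores(v, protein, self.logos_)
            if not self.include_diff_feature:
                ctx.pop("ctx_diff", None)
            for name, val in ctx.items():
                row[name] = val
                categories[name] = "context"
                kinds[name] = "numeric"

            unavailable = False
            for scale in self.scales:
                name = f"content_{scale.name}"
                val = content_average(v, protein, scale)
                if val is None:
                    unavailable = True
                    break
                row[name] = val
                categories[name] = "content"
                kinds[name] = "numeric"
            if unavailable:
                excluded.append(v.variant_id)
                continue

            for provider in self.providers:
                for name, val in provider.features(v, protein).items():
                    row[name] = float(val)
                    categories[name] = provider.category()
                    kinds[name] = (
                        "binary" if float(val) in (0.0, 1.0) and name.startswith(
                            ("gene_is_", "gene_flag_")
                        ) else "numeric"
                    )

            for name, val in position_features(v, protein).items():
                row[name] = val
                categories[name] = "position"
                kinds[name] = "numeric"
            flags = overlap_flags(
                v, tracks_by_protein.get(v.protein_id, ()), self.track_categories_
            )
            for cat, flag in flags.items():
                name = f"pos_overlap_{cat}"
                row[name] = float(flag)
                categories[name] = "position"
                kinds[name] = "binary"

            seg = extract_segments(v, protein)
            seg_rows.append(
                {
                    "deletion_seg": seg.deletion_seg,
                    "upstream_seg": seg.upstream_seg,
                    "downstream_seg": seg.downstream_seg,
                }
            )
            rows.append(row)
            labels.append(v.label)
            index.append(v.variant_id)

        data = pd.DataFrame(rows, index=index)
        # column order: canonical registry order, then the label
        rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
        ordered = sorted(
            data.columns, key=lambda n: (rank.get(categories.get(n, ""), 99), n)
        )
        data = data.reindex(columns=ordered)
        data["label"] = labels
        segments = pd.DataFrame(seg_rows, index=index) if seg_rows else None
        if excluded:
            logger.warning(
                "%d variant(s) excluded: prediction not possible "
                "(missing protein or provider feature)",
                len(excluded),
            )
        return FeatureTable(
            data=data,
            categories=categories,
            kinds=kinds,
            segments=segments,
            excluded=excluded,
        )


def featurize(
    variants: Sequence[DeletionVariant],
    proteins: Mapping[str, ProteinRecord],
    *,
    train_variants: Sequence[DeletionVariant] | None = None,
    scales: Sequence[PropertyScale] = (),
    tracks: Sequence[AnnotationTrack] = (),
    providers: Sequence[AnnotationProvider] = (),
    **kwargs,
) -> FeatureTable:
    """One-shot feature extraction.

    Logos are built from *train_variants* (defaulting to *variants* itself,
    appropriate only when featurizing the training set).
    """
    extractor = FeatureExtractor(
        proteins, scales=scales, tracks=tracks, providers=providers, **kwargs
    )
    extractor.fit(train_variants if train_variants is not None else variants)
    return extractor.transform(variants)
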