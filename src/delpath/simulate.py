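"""Synthetic proteomes, deletion variants, and feature tables.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without downloads:

* random protein sequences with planted annotation intervals (domains,
  disordered regions, repeats, transmembrane segments, secondary
  structure, last-exon windows);
* per-residue conservation and solvent accessibility correlated with
  domain membership (domains are conserved and buried);
* a random interaction graph and per-protein gene-class flags;
* labelled deletions whose class-conditional placement and length
  distributions mirror curated clinical data: pathogenic deletions sit
  preferentially in conserved/domain positions and are shorter (mean 2.71
  residues) than benign ones (mean 4.11), both classes having their mode
  at single-residue deletions; deletions never start at position 1.

Deletion lengths follow a geometric distribution truncated to [1, 10] with
the success parameter solved numerically to match the configured mean —
the simplest family consistent with a mode at 1 and the observed means.

:func:`simulate_feature_table` bypasses sequences entirely and emits a
numeric table with planted informative / duplicate / constant /
rare-binary columns, for direct tests of filtering and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from delpath.features import (
    FeatureTable,
    ProteinScalarProvider,
    ResidueTrackProvider,
    network_centralities,
)
from delpath.io import (
    AMINO_ACIDS,
    AnnotationTrack,
    DeletionVariant,
    NumericAnnotation,
    PropertyScale,
    ProteinRecord,
)

GENE_FLAGS = (
    "is_housekeeping",
    "is_haploinsufficient",
    "is_essential",
    "is_redundant",
    "is_pseudogene",
    "is_duplicated",
)

SECONDARY_CLASSES = ("helix", "strand", "turn_coil", "low_confidence")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the curated-data regime the pipeline targets: ~57/43
    pathogenic/benign balance, class-conditional deletion-length means of
    2.71 (pathogenic) and 4.11 (benign) residues truncated to [1, 10], and
    roughly two variants per protein.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (80, 400)
    n_variants: int = 400
    pathogenic_fraction: float = 0.577
    benign_length_mean: float = 4.11
    pathogenic_length_mean: float = 2.71
    max_deletion_length: int = 10
    domain_fraction: float = 0.30
    idr_fraction: float = 0.15
    placement_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pathogenic_fraction < 1:
            raise ValueError("pathogenic_fraction must be in (0, 1)")


@dataclass
class Proteome:
    """Everything :func:`simulate_proteome` plants for one synthetic study."""

    proteins: dict[str, ProteinRecord]
    tracks: list[AnnotationTrack] = field(default_factory=list)
    annotations: list[NumericAnnotation] = field(default_factory=list)
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    gene_flags: dict[str, dict[str, int]] = field(default_factory=dict)
    gene_age: dict[str, float] = field(default_factory=dict)


def truncated_geometric_p(mean: float, max_len: int = 10, tol: float = 1e-10) -> float:
    """Success parameter of a geometric distribution truncated to [1, max_len]
    whose mean equals *mean* (solved by bisection)."""
    if not 1.0 < mean < (max_len + 1) / 2.0:
        raise ValueError(
            f"mean must lie in (1, {(max_len + 1) / 2}) for a truncated geometric"
        )

    def trunc_mean(p: float) -> float:
        k = np.arange(1, max_len + 1)
        w = p * (1 - p) ** (k - 1)
        return float((k * w).sum() / w.sum())

    lo, hi = 1e-9, 1 - 1e-9  # mean decreases in p
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if trunc_mean(mid) > mean:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_lengths(
    rng: np.random.Generator, n: int, mean: float, max_len: int
) -> np.ndarray:
    p = truncated_geometric_p(mean, max_len)
    k = np.arange(1, max_len + 1)
    w = p * (1 - p) ** (k - 1)
    return rng.choice(k, size=n, p=w / w.sum())


def _plant_intervals(
    rng: np.random.Generator, length: int, coverage: float, mean_width: int
) -> list[tuple[int, int]]:
    """Random non-overlapping intervals covering roughly *coverage* of [1, L]."""
    target = coverage * length
    covered = np.zeros(length, dtype=bool)
    intervals: list[tuple[int, int]] = []
    attempts = 0
    while covered.sum() < target and attempts < 50:
        attempts += 1
        width = max(3, int(rng.poisson(mean_width)))
        # do not overshoot the coverage budget (short proteins especially)
        remaining = int(round(target - covered.sum()))
        width = min(width, max(3, remaining), length)
        start = int(rng.integers(1, length - width + 2))
        span = slice(start - 1, start - 1 + width)
        if covered[span].any():
            continue
        covered[span] = True
        intervals.append((start, start + width - 1))
    return sorted(intervals)


def simulate_proteome(config: SimConfig) -> Proteome:
    """Generate proteins with planted tracks, residue fields, and a graph.

    Deterministic for a fixed config (one seeded generator drives all
    randomness).  Domain residues get elevated conservation and reduced
    solvent accessibility; the substitution-pathogenicity field follows
    conservation with noise.
    """
    rng = np.random.default_rng(config.seed)
    proteome = Proteome(proteins={})
    letters = np.array(list(AMINO_ACIDS))
    for i in range(config.n_proteins):
        pid = f"SIM{i:05d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length))
        protein = ProteinRecord(pid, seq)
        proteome.proteins[pid] = protein

        domain = _plant_intervals(rng, length, config.domain_fraction, 40)
        idr = _plant_intervals(rng, length, config.idr_fraction, 25)
        repeat = _plant_intervals(rng, length, 0.06, 12)
        tracks = [
            AnnotationTrack(pid, "domain", domain),
            AnnotationTrack(pid, "IDR", idr),
            AnnotationTrack(pid, "repeat", repeat),
        ]
        if rng.random() < 0.25:
            tracks.append(AnnotationTrack(pid, "TM", _plant_intervals(rng, length, 0.05, 20)))
        # secondary structure: alternate stretches over the sequence
        pos = 1
        ss: dict[str, list[tuple[int, int]]] = {c: [] for c in SECONDARY_CLASSES}
        while pos <= length:
            cls = SECONDARY_CLASSES[int(rng.integers(len(SECONDARY_CLASSES)))]
            width = int(rng.integers(4, 15))
            end = min(length, pos + width - 1)
            ss[cls].append((pos, end))
            pos = end + 1
        for cls, iv in ss.items():
            if iv:
                tracks.append(AnnotationTrack(pid, f"ss_{cls}", iv))
        last_exon_start = max(1, int(length * 0.85))
        tracks.append(AnnotationTrack(pid, "last_exon", [(last_exon_start, length)]))
        proteome.tracks.extend(tracks)

        in_domain = np.zeros(length, dtype=bool)
        for s, e in domain:
            in_domain[s - 1 : e] = True
        conservation = rng.normal(2.0, 0.8, size=length) + 1.5 * in_domain
        conservation = np.clip(conservation, 0.0, None)
        sasa = np.clip(rng.normal(80.0, 25.0, size=length) - 35.0 * in_domain, 0.0, None)
        subst_path = np.clip(
            0.15 + 0.12 * conservation + rng.normal(0, 0.08, size=length), 0.0, 1.0
        )
        proteome.annotations.extend(
            [
                NumericAnnotation(pid, "conservation", conservation),
                NumericAnnotation(pid, "sasa", sasa),
                NumericAnnotation(pid, "substitution_pathogenicity", subst_path),
            ]
        )
        proteome.gene_flags[pid] = {
            flag: int(rng.random() < p)
            for flag, p in zip(GENE_FLAGS, (0.2, 0.1, 0.15, 0.1, 0.03, 0.25))
        }
        proteome.gene_age[pid] = float(rng.integers(1, 20))

    # sparse random interaction graph (~4 partners per protein)
    ids = sorted(proteome.proteins)
    n = len(ids)
    if n > 1:
        p_edge = min(1.0, 4.0 / (n - 1))
        upper = rng.random((n, n)) < p_edge
        for i in range(n):
            for j in range(i + 1, n):
                if upper[i, j]:
                    proteome.edges.append((ids[i], ids[j], float(rng.uniform(0.2, 1.0))))
    return proteome


def simulate_variants(proteome: Proteome, config: SimConfig) -> list[DeletionVariant]:
    """Sample labelled deletions with class-dependent placement and length.

    Pathogenic deletions are placed with probability proportional to
    ``exp(separation · conservation_z)`` of the start residue — favouring
    conserved, domain, buried positions; benign deletions use the negated
    weighting, pushing them towards termini, disordered and repeat regions
    (which are less conserved by construction).  ``placement_separation``
    of 0 makes placement class-independent.  Deletions too long for their
    protein are resampled; position 1 is never deleted.
    """
    rng = np.random.default_rng(config.seed + 1)
    cons = {
        a.protein_id: np.asarray(a.values, dtype=float)
        for a in proteome.annotations
        if a.name == "conservation"
    }
    ids = sorted(proteome.proteins)
    variants: list[DeletionVariant] = []
    used: set[tuple[str, int, int]] = set()
    labels = rng.random(config.n_variants) < config.pathogenic_fraction
    n_path = int(labels.sum())
    lengths = np.empty(config.n_variants, dtype=int)
    lengths[labels] = _sample_lengths(
        rng, n_path, config.pathogenic_length_mean, config.max_deletion_length
    )
    lengths[~labels] = _sample_lengths(
        rng,
        config.n_variants - n_path,
        config.benign_length_mean,
        config.max_deletion_length,
    )
    for i in range(config.n_variants):
        label = "pathogenic" if labels[i] else "benign"
        for _ in range(200):  # resample until a valid placement is found
            pid = ids[int(rng.integers(len(ids)))]
            protein = proteome.proteins[pid]
            length = int(lengths[i])
            if protein.length < length + 1:
                continue
            starts = np.arange(2, protein.length - length + 2)
            c = cons[pid][starts - 1]
            z = (c - c.mean()) / (c.std() + 1e-9)
            sign = 1.0 if label == "pathogenic" else -1.0
            w = np.exp(sign * config.placement_separation * z)
            start = int(rng.choice(starts, p=w / w.sum()))
            key = (pid, start, start + length - 1)
            if key in used:
                continue
            used.add(key)
            variants.append(
                DeletionVariant(pid, start, start + length - 1, label=label, source="sim")
            )
            break
        else:
            raise RuntimeError("could not place a variant; proteome too small")
    return variants


def providers_for(proteome: Proteome):
    """Standard provider stack for a simulated proteome."""
    centralities = network_centralities(proteome.edges)
    scalars: dict[str, dict[str, float]] = {}
    for pid in proteome.proteins:
        vals: dict[str, float] = {f"flag_{k}": float(v) for k, v in proteome.gene_flags[pid].items()}
        vals["age"] = proteome.gene_age[pid]
        cent = centralities.get(pid)
        for name in ("degree", "closeness", "betweenness", "harmonic", "hub_score", "power"):
            vals[f"ppi_{name}"] = float(cent[name]) if cent else 0.0
        scalars[pid] = vals
    return [
        ResidueTrackProvider("conservation", proteome.annotations),
        ResidueTrackProvider("sasa", proteome.annotations),
        ResidueTrackProvider("substitution_pathogenicity", proteome.annotations),
        ProteinScalarProvider(scalars, category="gene", prefix="gene_"),
    ]


def example_scales() -> list[PropertyScale]:
    """Three classical physicochemical scales for content averages."""
    hydropathy = {  # Kyte-Doolittle
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    }
    volume = {  # residue volumes (A^3)
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    }
    polarity = {  # Zimmerman polarity
        "A": 0.0, "R": 52.0, "N": 3.38, "D": 49.7, "C": 1.48, "Q": 3.53,
        "E": 49.9, "G": 0.0, "H": 51.6, "I": 0.13, "L": 0.13, "K": 49.5,
        "M": 1.43, "F": 0.35, "P": 1.58, "S": 1.67, "T": 1.66, "W": 2.1,
        "Y": 1.61, "V": 0.13,
    }
    return [
        PropertyScale("HYDROPATHY_KD", hydropathy),
        PropertyScale("VOLUME", volume),
        PropertyScale("POLARITY_ZIM", polarity),
    ]


def simulate_feature_table(
    n_rows: int = 1000,
    n_features: int = 50,
    n_informative: int = 5,
    effect: float = 1.0,
    seed: int = 0,
    pathogenic_fraction: float = 0.5,
    n_duplicate: int = 0,
    n_constant: int = 0,
    n_rare_binary: int = 0,
    n_correlated: int = 0,
) -> FeatureTable:
    """Numeric feature table with planted structure.

    The first *n_informative* columns (``inf_*``) are shifted between
    classes by *effect* standard deviations; the rest (``noise_*``) carry
    no signal.  Optional planted columns exercise the filter cascade:
    duplicates of informative columns, constants, binary columns with tiny
    minorities, and monotone transforms of existing columns.  Each row is
    its own synthetic protein, so protein-disjoint machinery degenerates to
    plain row splitting.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    y = rng.random(n_rows) < pathogenic_fraction
    X = rng.normal(size=(n_rows, n_features))
    X[:, :n_informative] += effect * y[:, None]

    names = [f"inf_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:03d}" for i in range(n_features - n_informative)
    ]
    df = pd.DataFrame(X, columns=names)
    kinds = {name: "numeric" for name in names}
    for i in range(n_duplicate):
        src = names[i % max(1, n_informative)]
        df[f"dup_{i:02d}"] = df[src]
        kinds[f"dup_{i:02d}"] = "numeric"
    for i in range(n_constant):
        df[f"const_{i:02d}"] = 3.14
        kinds[f"const_{i:02d}"] = "numeric"
    for i in range(n_rare_binary):
        col = np.zeros(n_rows)
        col[rng.choice(n_rows, size=min(5, n_rows), replace=False)] = 1.0
        df[f"rare_{i:02d}"] = col
        kinds[f"rare_{i:02d}"] = "binary"
    for i in range(n_correlated):
        src = df[names[i % len(names)]]
        df[f"mono_{i:02d}"] = src**3 + 1.0
        kinds[f"mono_{i:02d}"] = "numeric"

    df.index = [f"SP{i:05d}:2-3" for i in range(n_rows)]
    df["label"] = np.where(y, "pathogenic", "benign")
    categories = {name: "content" for name in df.columns if name != "label"}
    return FeatureTable(data=df, categories=categories, kinds=kinds)
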