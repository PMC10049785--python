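"""Accuracy protocol: crop known-placement parents into fragments and score.

Long "parent" molecules with exactly known genomic placement are digitally
cropped into random fragments; each fragment inherits its parent's placement
shifted by the crop offset, is pushed through localization and alignment,
and the fraction of correct placements per fragment length is reported with
exact (Clopper-Pearson) 95% binomial confidence bounds.

Parents here are simulated molecules (placement known by construction),
which preserves the protocol's logic without any external alignment tool.
The protocol works identically on image fragments (full pipeline) and on
label-list fragments (aligner-only evaluation of localization lists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .aligner import Alignment, AlignmentParams, QueryMap, ReferenceMap, align_to_genome
from .simulator import (
    GroundTruthLabels,
    MoleculeImage,
    SimulationConfig,
    _dedupe_bp,
    _positions_bp_to_px,
    _resolve_pixel_collisions,
    render_image,
)

__all__ = [
    "Parent",
    "Fragment",
    "simulate_genome_references",
    "simulate_parents",
    "make_ground_truth_fragments",
    "is_correct_alignment",
    "clopper_pearson_interval",
    "success_rate_curve",
    "run_synthetic_evaluation",
]


@dataclass(frozen=True)
class Parent:
    """A long molecule with exactly known genomic placement."""

    molecule: MoleculeImage | QueryMap
    sequence_id: str
    start_bp: float
    pixel_size_bp: float

    @property
    def length_px(self) -> float:
        if isinstance(self.molecule, MoleculeImage):
            return float(self.molecule.length_px)
        return float(self.molecule.molecule_length_px)


@dataclass(frozen=True)
class Fragment:
    """A cropped fragment and its inherited true placement."""

    molecule: MoleculeImage | QueryMap
    sequence_id: str
    true_interval_bp: tuple[float, float]
    fragment_length_bp: float
    fragment_id: str = "frag"

    @property
    def true_midpoint_bp(self) -> float:
        a, b = self.true_interval_bp
        return 0.5 * (a + b)


def simulate_genome_references(
    genome_length_bp: int,
    n_chromosomes: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[ReferenceMap]:
    """Draw motif maps for a synthetic genome split into equal chromosomes."""
    chrom_len = genome_length_bp // n_chromosomes
    refs = []
    for c in range(n_chromosomes):
        k = rng.binomial(chrom_len, config.emitter_density)
        sites = np.sort(
            _dedupe_bp(rng.integers(0, chrom_len, size=k).astype(np.float64), chrom_len, rng)
        )
        refs.append(
            ReferenceMap(positions_bp=sites, sequence_id=f"chr{c + 1}", sequence_length_bp=chrom_len)
        )
    return refs


def simulate_parents(
    references: list[ReferenceMap],
    n_parents: int,
    parent_length_bp: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[Parent]:
    """Render long parent molecules from random genomic intervals.

    Each parent images exactly the reference motif sites inside its interval
    (re-based to the molecule origin) under the standard noise model, so its
    placement is known exactly.
    """
    parents = []
    for _ in range(n_parents):
        ref = references[int(rng.integers(0, len(references)))]
        start = int(rng.integers(0, ref.sequence_length_bp - parent_length_bp + 1))
        sites = ref.positions_bp
        inside = sites[(sites >= start) & (sites < start + parent_length_bp)] - start
        length_px = int(np.ceil(parent_length_bp / config.pixel_size_bp))
        local_bp = _resolve_pixel_collisions(
            inside.copy(), parent_length_bp, config.pixel_size_bp, rng
        )
        labels = GroundTruthLabels.from_positions(
            _positions_bp_to_px(local_bp, config), length_px
        )
        image = render_image(labels, length_px, config, rng)
        parents.append(
            Parent(
                molecule=image,
                sequence_id=ref.sequence_id,
                start_bp=float(start),
                pixel_size_bp=config.pixel_size_bp,
            )
        )
    return parents


def _crop_parent(parent: Parent, window_start_px: int, window_len_px: int):
    mol = parent.molecule
    if isinstance(mol, MoleculeImage):
        return MoleculeImage(
            mol.intensities[:, window_start_px:window_start_px + window_len_px],
            mol.config,
        )
    pos = mol.positions_px
    keep = (pos >= window_start_px) & (pos < window_start_px + window_len_px)
    return QueryMap(
        positions_px=pos[keep] - window_start_px,
        molecule_id=mol.molecule_id,
        molecule_length_px=float(window_len_px),
    )


def make_ground_truth_fragments(
    parents: list[Parent],
    fragment_lengths_bp: list[float],
    n_per_length: int,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Crop parents into random fragments with inherited true placement.

    For each requested length, ``n_per_length`` fragments are cut at
    uniformly random window offsets from randomly chosen (long-enough)
    parents; each fragment's true genomic interval is the parent placement
    shifted by the window offset.
    """
    fragments = []
    for frag_bp in fragment_lengths_bp:
        eligible = [
            p for p in parents if p.length_px * p.pixel_size_bp >= frag_bp
        ]
        if not eligible:
            raise ValueError(f"no parent is long enough for a {frag_bp} bp fragment")
        for t in range(n_per_length):
            parent = eligible[int(rng.integers(0, len(eligible)))]
            frag_px = int(round(frag_bp / parent.pixel_size_bp))
            max_start = int(parent.length_px) - frag_px
            w = int(rng.integers(0, max_start + 1))
            mol = _crop_parent(parent, w, frag_px)
            start_bp = parent.start_bp + w * parent.pixel_size_bp
            fragments.append(
                Fragment(
                    molecule=mol,
                    sequence_id=parent.sequence_id,
                    true_interval_bp=(start_bp, start_bp + frag_bp),
                    fragment_length_bp=float(frag_bp),
                    fragment_id=f"L{int(frag_bp)}_{t}",
                )
            )
    return fragments


def is_correct_alignment(
    alignment: Alignment,
    truth_sequence_id: str,
    truth_interval_bp: tuple[float, float],
    tolerance_bp: float | None = None,
    truth_orientation: str | None = "forward",
) -> bool:
    """Correct iff same sequence, same orientation class, midpoint within
    tolerance (default: half the fragment length; closed boundary)."""
    if alignment.sequence_id != truth_sequence_id:
        return False
    if truth_orientation is not None and alignment.orientation != truth_orientation:
        return False
    a, b = truth_interval_bp
    if tolerance_bp is None:
        tolerance_bp = 0.5 * (b - a)
    mid_true = 0.5 * (a + b)
    mid_aln = 0.5 * (alignment.ref_interval_bp[0] + alignment.ref_interval_bp[1])
    return abs(mid_aln - mid_true) <= tolerance_bp


def clopper_pearson_interval(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta-distribution quantiles.

    ``low = BetaQuantile(a/2; k, n-k+1)`` (0 when k = 0) and
    ``high = BetaQuantile(1-a/2; k+1, n-k)`` (1 when k = n).
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n and n >= 1")
    a = 1.0 - confidence
    low = 0.0 if k == 0 else float(beta_dist.ppf(a / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - a / 2, k + 1, n - k))
    return low, high


def success_rate_curve(
    fragments: list[Fragment],
    references: list[ReferenceMap],
    params: AlignmentParams | None = None,
    *,
    localizer_model=None,
    threshold: float | None = None,
    tolerance_bp: float | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Align every fragment and tabulate success rate per fragment length.

    Image fragments require ``localizer_model``; label-list fragments are
    aligned directly.  Fragments whose query map comes out empty count as
    incorrect.  Returns a tidy table with one row per fragment length:
    n_trials, n_correct, success_rate and Clopper-Pearson bounds.
    """
    if not fragments:
        raise ValueError("no fragments to evaluate")
    params = params or AlignmentParams()
    from .localizer import localize  # local import: localizer depends on aligner

    records = []
    for frag in fragments:
        if isinstance(frag.molecule, QueryMap):
            query = frag.molecule
        else:
            if localizer_model is None:
                raise ValueError("image fragments require a localizer model")
            query = localize(frag.molecule, localizer_model, threshold, frag.fragment_id)
        if query.positions_px.size == 0:
            correct = False
        else:
            best, _ = align_to_genome(query, references, params)
            correct = is_correct_alignment(
                best, frag.sequence_id, frag.true_interval_bp, tolerance_bp
            )
        records.append((frag.fragment_length_bp, correct))

    rows = []
    df = pd.DataFrame(records, columns=["fragment_length_bp", "correct"])
    for length, group in df.groupby("fragment_length_bp", sort=True):
        n = len(group)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty bin at {length} bp excluded")
            continue
        k = int(group["correct"].sum())
        low, high = clopper_pearson_interval(k, n, confidence)
        rows.append(
            {
                "fragment_length_bp": length,
                "n_trials": n,
                "n_correct": k,
                "success_rate": k / n,
                "ci_low": low,
                "ci_high": high,
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_evaluation(
    *,
    genome_length_bp: int = 20_000_000,
    n_chromosomes: int = 4,
    parent_length_bp: int = 450_000,
    n_parents: int = 32,
    fragment_lengths_bp: tuple[float, ...] = (25_000, 50_000, 100_000, 150_000),
    n_per_length: int = 128,
    sim_config: SimulationConfig | None = None,
    align_params: AlignmentParams | None = None,
    localizer_model=None,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end synthetic protocol: genome -> parents -> fragments -> curve."""
    sim_config = sim_config or SimulationConfig()
    align_params = align_params or AlignmentParams(scale_bp_per_px=sim_config.pixel_size_bp)
    rng = np.random.default_rng(seed)
    references = simulate_genome_references(genome_length_bp, n_chromosomes, sim_config, rng)
    parents = simulate_parents(references, n_parents, parent_length_bp, sim_config, rng)
    fragments = make_ground_truth_fragments(
        parents, list(fragment_lengths_bp), n_per_length, rng
    )
    return success_rate_curve(
        fragments, references, align_params, localizer_model=localizer_model
    )
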