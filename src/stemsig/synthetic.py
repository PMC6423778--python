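"""Synthetic inputs with planted ground truth.

Three generators emulate the study's raw materials so every downstream
stage is testable without external downloads:

* :func:`generate_bead_summary` -- a bead-summary expression matrix over
  five sample groups (fMSC, aMSC, iPSC, iMSC, ESC) with log-normal
  signals, a population of unexpressed genes at negative-control level,
  and planted aging/rejuvenation signature genes.
* :func:`generate_membrane` -- a grayscale cytokine-array membrane with
  radially symmetric spots whose integrated intensity is proportional to
  planted abundance, reference spots defining the 100% scale.
* :func:`generate_interaction_file` -- a planted-partition protein
  interaction file in BioGRID TAB style with decoy taxonomy rows.

The signal model is log-normal: expressed genes draw log2 signals around
``signal_mu`` and unexpressed genes around ``null_mu``; negative controls
draw from the same null distribution, which makes downstream detection
p-values calibrated by construction.  Planted rejuvenation genes are
expressed in iMSC/iPSC (and ESC) samples only; planted aging genes in
fMSC/aMSC samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stemsig.microarray import BeadSummaryMatrix
from stemsig.network import COL_ORG_A, COL_ORG_B, COL_SYM_A, COL_SYM_B
from stemsig.secretome import MembraneLayout, Spot

GROUPS = ("fMSC", "aMSC", "iPSC", "iMSC", "ESC")
AGING_GROUPS = ("fMSC", "aMSC")
REJUVENATION_GROUPS = ("iPSC", "iMSC", "ESC")

#: integrated spot intensity (counts) at reference abundance 1.0
REFERENCE_INTEGRAL = 200_000.0


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Bead-summary simulation settings.

    Every gene (and every negative-control bead) carries a log2 *level*
    drawn once and shared across samples -- around ``signal_mu`` with
    spread ``signal_sigma`` where the gene is expressed, around
    ``null_mu`` with spread ``null_sigma`` where it is not.  Each
    observed signal adds per-sample multiplicative (log2-additive) noise
    of spread ``noise_sigma`` on top of the level.  The default effect
    size is 4 log2 units.  ``n_neg_controls`` defaults to 1000 because
    detection-p granularity is 1/(n+1): n >= 999 is required for the
    signature threshold p < 0.001 to be attainable at all.
    """

    n_genes: int = 1000
    n_neg_controls: int = 1000
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "fMSC": 3,
            "aMSC": 3,
            "iPSC": 3,
            "iMSC": 3,
            "ESC": 2,
        }
    )
    frac_expressed: float = 0.4
    planted_aging: list[str] = field(default_factory=list)
    planted_rejuvenation: list[str] = field(default_factory=list)
    signal_mu: float = 11.0
    signal_sigma: float = 0.5
    null_mu: float = 7.0
    null_sigma: float = 0.25
    noise_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_neg_controls < 1:
            raise ConfigError("n_genes and n_neg_controls must be >= 1")
        unknown = set(self.samples_per_group) - set(GROUPS)
        if unknown:
            raise ConfigError(f"unknown groups: {sorted(unknown)}")
        if any(n < 1 for n in self.samples_per_group.values()):
            raise ConfigError("every group needs >= 1 sample")
        if not 0 < self.frac_expressed < 1:
            raise ConfigError("frac_expressed must lie in (0, 1)")
        universe = set(self.gene_ids)
        planted = set(self.planted_aging) | set(self.planted_rejuvenation)
        if not planted <= universe:
            raise ConfigError("planted genes outside the gene universe")
        if set(self.planted_aging) & set(self.planted_rejuvenation):
            raise ConfigError("planted aging and rejuvenation lists overlap")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @classmethod
    def with_planted(
        cls, n_aging: int = 50, n_rejuvenation: int = 50, **kwargs
    ) -> "SimConfig":
        """Config with the first genes assigned to the planted signatures."""
        cfg = cls(**kwargs)
        ids = cfg.gene_ids
        if n_aging + n_rejuvenation > len(ids):
            raise ConfigError("planted lists exceed the gene universe")
        return cls(
            **{
                **kwargs,
                "planted_aging": ids[:n_aging],
                "planted_rejuvenation": ids[n_aging : n_aging + n_rejuvenation],
            }
        )


@dataclass
class GroundTruth:
    """Planted truth attached to a generated fixture."""

    expressed: pd.DataFrame | None = None  # genes x groups booleans
    signature_label: dict[str, str] = field(default_factory=dict)
    community_label: dict[str, int] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, int] = field(default_factory=dict)


def generate_bead_summary(
    config: SimConfig,
) -> tuple[BeadSummaryMatrix, GroundTruth]:
    """Draw a bead-summary matrix plus its negative controls.

    Non-planted genes are expressed in all groups with probability
    ``frac_expressed`` or in none; planted genes follow their signature
    pattern.  Identical seeds give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    groups_of_samples: dict[str, str] = {}
    sample_ids: list[str] = []
    for g in GROUPS:
        for k in range(config.samples_per_group.get(g, 0)):
            sid = f"{g}_{k + 1}"
            sample_ids.append(sid)
            groups_of_samples[sid] = g

    aging = set(config.planted_aging)
    rejuvenation = set(config.planted_rejuvenation)
    background_expressed = rng.random(len(genes)) < config.frac_expressed

    expressed = pd.DataFrame(False, index=genes, columns=list(GROUPS))
    labels: dict[str, str] = {}
    for i, gene in enumerate(genes):
        if gene in aging:
            expressed.loc[gene, list(AGING_GROUPS)] = True
            labels[gene] = "aging"
        elif gene in rejuvenation:
            expressed.loc[gene, list(REJUVENATION_GROUPS)] = True
            labels[gene] = "rejuvenation"
        else:
            expressed.loc[gene, :] = bool(background_expressed[i])
            labels[gene] = "none"

    exp_mask = np.column_stack(
        [expressed[groups_of_samples[s]].to_numpy() for s in sample_ids]
    )
    # per-gene levels, drawn once and shared across the samples of each
    # expression state; controls get per-bead levels from the same null
    level_expressed = rng.normal(
        config.signal_mu, config.signal_sigma, size=len(genes)
    )
    level_null = rng.normal(config.null_mu, config.null_sigma, size=len(genes))
    level = np.where(exp_mask, level_expressed[:, None], level_null[:, None])
    log2_signals = level + rng.normal(0.0, config.noise_sigma, size=level.shape)
    bead_level = rng.normal(
        config.null_mu, config.null_sigma, size=config.n_neg_controls
    )
    log2_controls = bead_level[:, None] + rng.normal(
        0.0, config.noise_sigma, size=(config.n_neg_controls, len(sample_ids))
    )

    signals = pd.DataFrame(
        np.exp2(log2_signals), index=genes, columns=sample_ids
    )
    controls = pd.DataFrame(
        np.exp2(log2_controls),
        index=[f"NC{i + 1}" for i in range(config.n_neg_controls)],
        columns=sample_ids,
    )
    matrix = BeadSummaryMatrix(signals, controls, groups_of_samples)
    truth = GroundTruth(expressed=expressed, signature_label=labels)
    return matrix, truth


# ---------------------------------------------------------------------------
# cytokine membranes
# ---------------------------------------------------------------------------


def grid_layout(
    analytes: list[str],
    radius: float = 8.0,
    pitch: float | None = None,
    n_cols: int = 10,
    duplicate_references: bool = True,
) -> MembraneLayout:
    """Regular grid layout with reference spots in three corner positions.

    Reference positions are labelled ``REF_UL`` (upper left, first row),
    ``REF_LL`` and ``REF_LR`` (lower row corners); each position holds a
    duplicate pair when ``duplicate_references`` is set, mirroring kit
    membranes.  ``pitch`` defaults to 4x the spot radius, which keeps the
    background annuli clear of neighbouring discs.
    """
    pitch = 4 * radius if pitch is None else pitch
    spots: list[Spot] = []

    def cell(row: int, col: int) -> tuple[float, float]:
        return pitch * (col + 1), pitch * (row + 1)

    n_ref_dup = 2 if duplicate_references else 1
    # upper-left references occupy the first cells of row 0
    for j in range(n_ref_dup):
        x, y = cell(0, j)
        spots.append(Spot("REF_UL", 0, j, x, y, radius, True))

    row, col = 0, n_ref_dup
    for analyte in analytes:
        if col >= n_cols:
            row, col = row + 1, 0
        x, y = cell(row, col)
        spots.append(Spot(analyte, row, col, x, y, radius, False))
        col += 1

    last = row + 1  # dedicated bottom row for the two lower positions
    for j in range(n_ref_dup):
        x, y = cell(last, j)
        spots.append(Spot("REF_LL", last, j, x, y, radius, True))
    for j in range(n_ref_dup):
        x, y = cell(last, n_cols - 1 - j)
        spots.append(Spot("REF_LR", last, n_cols - 1 - j, x, y, radius, True))
    return MembraneLayout(spots)


def generate_membrane(
    profile: dict[str, float],
    layout: MembraneLayout,
    seed: int = 0,
    background: float = 500.0,
    noise_sigma: float = 20.0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render a 16-bit grayscale membrane image.

    Each spot is a radially symmetric Gaussian blob (sigma = radius / 4)
    whose integrated intensity is ``abundance * REFERENCE_INTEGRAL``
    counts; reference spots render at abundance 1.0, which defines the
    100% scale.  ``profile`` maps analyte label -> abundance; analytes
    absent from the profile render at 0.
    """
    rng = np.random.default_rng(seed)
    if shape is None:
        max_x = max(s.x + 2 * s.radius for s in layout.spots)
        max_y = max(s.y + 2 * s.radius for s in layout.spots)
        shape = (int(np.ceil(max_y)) + 8, int(np.ceil(max_x)) + 8)
    h, w = shape
    for s in layout.spots:
        if not (2 * s.radius <= s.x <= w - 2 * s.radius) or not (
            2 * s.radius <= s.y <= h - 2 * s.radius
        ):
            raise ValueError(f"spot {s.analyte} outside image bounds")

    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for spot in layout.spots:
        abundance = 1.0 if spot.is_reference else float(
            profile.get(spot.analyte, 0.0)
        )
        if abundance < 0:
            raise ValueError(f"negative abundance for {spot.analyte}")
        if abundance == 0:
            continue
        sigma = spot.radius / 4.0
        r2 = (xx - spot.x) ** 2 + (yy - spot.y) ** 2
        blob = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
        img += abundance * REFERENCE_INTEGRAL * blob
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.round(img).clip(0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# protein interaction files
# ---------------------------------------------------------------------------


def generate_interaction_file(
    n_communities: int,
    sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
    path=None,
    n_decoys: int = 5,
    decoy_taxid: int = 10090,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Planted-partition interaction records in BioGRID TAB style.

    Nodes ``C<c>N<i>`` belong to community ``c``; within-community pairs
    interact with probability ``p_in``, cross-community pairs with
    ``p_out``.  ``n_decoys`` extra rows carry a non-human taxonomy ID to
    exercise the taxid filter.  Writes a tab-delimited file when ``path``
    is given and returns the records plus the planted community labels.
    """
    if len(sizes) != n_communities:
        raise ConfigError("sizes must list one size per community")
    if sum(sizes) == 0:
        raise ConfigError("community sizes sum to 0")
    if not p_in > p_out:
        raise ConfigError("planted partition requires p_in > p_out")
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    community: dict[str, int] = {}
    for c, size in enumerate(sizes):
        for i in range(size):
            name = f"C{c + 1}N{i + 1}"
            nodes.append(name)
            community[name] = c
    rows = []
    n_edges = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            p = p_in if community[a] == community[b] else p_out
            if rng.random() < p:
                rows.append((a, b, 9606, 9606))
                n_edges += 1
    for d in range(n_decoys):
        rows.append((f"MM{d + 1}A", f"MM{d + 1}B", decoy_taxid, decoy_taxid))
    records = pd.DataFrame(
        rows, columns=[COL_SYM_A, COL_SYM_B, COL_ORG_A, COL_ORG_B]
    )
    if path is not None:
        records.to_csv(path, sep="\t", index=False)
    truth = GroundTruth(
        community_label=community,
        provenance={"n_records": len(rows), "n_edges": n_edges, "n_decoys": n_decoys},
    )
    return records, truth
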