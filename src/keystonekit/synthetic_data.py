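"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure each stage assumes:
bead-array-scale expression matrices (log-normal intensities, n = 3 per
group, planted fold-changes), gene-word corpora with planted gene-theme
co-occurrence, two-channel islet images with known ellipse geometry and
channel split, and paired protein lists with an exact planted overlap.
Every generator is a pure function of its parameters and seed, and returns
a :class:`SyntheticTruth` that fully reconstructs what was planted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ChannelImage, Corpus, ExpressionMatrix
from .islet_morphometry import IsletRoi


@dataclass
class SyntheticTruth:
    """Planted ground truth; serialised beside each generated dataset."""

    seed: int
    generator: str
    params: dict = field(default_factory=dict)
    planted_de_genes: dict[str, float] = field(default_factory=dict)
    planted_theme_map: dict[str, list[str]] = field(default_factory=dict)
    planted_pleiotropic: list[str] = field(default_factory=list)
    planted_islets: list[dict] = field(default_factory=list)
    planted_overlap: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# expression


def gen_expression(
    n_genes: int = 22000,
    groups: Sequence[str] = ("WT", "KO"),
    n_per_group: int = 3,
    n_de: int = 200,
    lfc_sd: float = 0.5,
    noise_sd: float = 0.25,
    lfc_min: float | None = None,
    perturbed_groups: Sequence[str] | None = None,
    baseline_mean: float = 2.5,
    baseline_sd: float = 0.6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log10-normal intensity matrix with ``n_de`` planted differential genes.

    Planted genes receive a signed log10 shift of magnitude
    ``lfc_min + |N(0, lfc_sd)|`` (``lfc_min`` defaults to ``2 * noise_sd``,
    i.e. planted effects are clearly separated from residual noise — a
    >=3-fold change at the default noise level, the scale of regulation
    array studies plant and report) in every perturbed group (default:
    every group except the first, which acts as reference).
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if len(set(groups)) != len(groups) or len(groups) < 2:
        raise ValueError("groups must be >=2 unique labels")
    if lfc_min is None:
        lfc_min = 2.0 * noise_sd
    perturbed = set(perturbed_groups) if perturbed_groups is not None else set(groups[1:])
    unknown = perturbed - set(groups)
    if unknown:
        raise ValueError(f"perturbed groups not in groups: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"{g}_s{j + 1}" for g in groups for j in range(n_per_group)]
    group_map = {s: s.rsplit("_s", 1)[0] for s in sample_ids}

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = signs * (lfc_min + np.abs(rng.normal(0.0, lfc_sd, size=n_de)))

    shift = np.zeros((n_genes, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        if group_map[s] in perturbed:
            shift[de_idx, j] = lfc
    log_vals = (
        baseline[:, None] + shift + rng.normal(0.0, noise_sd, size=shift.shape)
    )
    matrix = ExpressionMatrix(gene_ids, sample_ids, 10.0 ** log_vals, group_map)
    truth = SyntheticTruth(
        seed=seed,
        generator="expression",
        params={
            "n_genes": n_genes, "groups": list(groups), "n_per_group": n_per_group,
            "n_de": n_de, "lfc_sd": lfc_sd, "noise_sd": noise_sd,
            "lfc_min": lfc_min, "perturbed_groups": sorted(perturbed),
            "baseline_mean": baseline_mean, "baseline_sd": baseline_sd,
        },
        planted_de_genes={gene_ids[i]: float(f) for i, f in zip(de_idx, lfc)},
    )
    return matrix, truth


# --------------------------------------------------------------------------
# corpus


def gen_corpus(
    genes: Sequence[str] | int = 200,
    vocab_size: int = 500,
    themes: Mapping[str, Sequence[str]] | None = None,
    seeded_genes: Mapping[str, Sequence[str]] | None = None,
    n_seeded_per_theme: int = 20,
    doc_len_mean: float = 80.0,
    marker_rate: float = 0.3,
    zipf_exponent: float = 1.05,
    split_marker_budget: bool = True,
    seed: int = 0,
) -> tuple[Corpus, SyntheticTruth]:
    """Gene-word documents: Zipf-distributed background vocabulary, with
    theme marker terms planted at rate ``marker_rate`` into seeded genes.

    ``themes`` maps a theme label to its marker terms; ``seeded_genes`` maps
    the theme to the genes carrying it (drawn disjointly at random when
    omitted).  Document lengths are Poisson(``doc_len_mean``), floored at 5.
    """
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        gene_ids = [f"Gene{i:04d}" for i in range(genes)]
    else:
        gene_ids = list(genes)
    if themes is None:
        themes = {
            "glycemic": ["insulin", "glucose", "incretin"],
            "dna-repair": ["dna-damage", "repair", "helicase"],
        }
    themes = {k: list(v) for k, v in themes.items()}

    if seeded_genes is None:
        pool = list(gene_ids)
        rng.shuffle(pool)
        seeded_genes = {}
        cursor = 0
        for theme in themes:
            seeded_genes[theme] = pool[cursor : cursor + n_seeded_per_theme]
            cursor += n_seeded_per_theme
    seeded_genes = {k: list(v) for k, v in seeded_genes.items()}

    gene_theme: dict[str, list[str]] = {}
    for theme, gs in seeded_genes.items():
        for g in gs:
            gene_theme.setdefault(g, []).append(theme)

    background = [f"word{i:04d}" for i in range(vocab_size)]
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    probs = ranks ** (-zipf_exponent)
    probs /= probs.sum()

    documents: dict[str, Counter] = {}
    for g in gene_ids:
        length = max(5, int(rng.poisson(doc_len_mean)))
        tokens = [background[i] for i in rng.choice(vocab_size, size=length, p=probs)]
        g_themes = gene_theme.get(g, [])
        for theme in g_themes:
            markers = themes[theme]
            # with a split budget a multi-theme gene mentions each theme more
            # thinly (fixed document length); unsplit, its document grows —
            # the model of a hub gene with a richer literature
            denom = len(g_themes) if split_marker_budget else 1
            n_markers = max(1, int(round(marker_rate * length / denom)))
            for i in rng.integers(0, len(markers), size=n_markers):
                tokens.append(markers[int(i)])
        documents[g] = Counter(tokens)
    corpus = Corpus(documents)
    truth = SyntheticTruth(
        seed=seed,
        generator="corpus",
        params={
            "vocab_size": vocab_size, "themes": {k: list(v) for k, v in themes.items()},
            "doc_len_mean": doc_len_mean, "marker_rate": marker_rate,
            "zipf_exponent": zipf_exponent,
            "split_marker_budget": split_marker_budget,
            "seeded_genes": {k: list(v) for k, v in seeded_genes.items()},
        },
        planted_theme_map={g: sorted(t) for g, t in gene_theme.items()},
    )
    return corpus, truth


def gen_pleiotropic_corpus(
    n_genes: int = 1600,
    n_themes: int = 5,
    n_pleiotropic: int = 10,
    n_background_seeded: int = 1200,
    theme_vocab_size: int = 40,
    vocab_size: int = 500,
    doc_len_mean: float = 80.0,
    marker_rate: float = 0.25,
    recommended_rank: int = 400,
    seed: int = 0,
) -> tuple[Corpus, SyntheticTruth]:
    """Corpus where a few genes span *all* themes (planted pleiotropic /
    keystone candidates) while background-seeded genes carry exactly two.

    Each theme owns a ``theme_vocab_size``-word sub-vocabulary (pathway
    literatures have vocabularies, not just one marker word); a theme's
    interrogation query is its first word.  Background genes model ordinary
    pathway members: each is seeded with two themes, so it clears a
    two-pathway association filter but never approaches the pleiotropic
    class, and there are enough of them that the pleiotropic genes sit
    beyond the 99th percentile of the retained population (class-percentile
    selection needs the top class to be <1% of retained rows).  Pleiotropic
    genes are seeded with every theme at full budget (a hub gene's
    literature is richer, not thinner per topic).  ``recommended_rank`` is
    the decomposition rank at which the planted themes stay separable at
    the implicit-association threshold; it is stored in the truth record.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"Gene{i:04d}" for i in range(n_genes)]
    themes = {
        f"theme{t:02d}": [
            f"theme{t:02d}-word{w:02d}" for w in range(theme_vocab_size)
        ]
        for t in range(n_themes)
    }
    pool = list(gene_ids)
    rng.shuffle(pool)
    pleio = pool[:n_pleiotropic]
    doubles = pool[n_pleiotropic : n_pleiotropic + n_background_seeded]
    seeded: dict[str, list[str]] = {t: list(pleio) for t in themes}
    for i, g in enumerate(doubles):
        seeded[f"theme{i % n_themes:02d}"].append(g)
        seeded[f"theme{(i + 1) % n_themes:02d}"].append(g)
    corpus, truth = gen_corpus(
        genes=gene_ids,
        vocab_size=vocab_size,
        themes=themes,
        seeded_genes=seeded,
        doc_len_mean=doc_len_mean,
        marker_rate=marker_rate,
        split_marker_budget=False,
        seed=seed,
    )
    truth.generator = "pleiotropic-corpus"
    truth.planted_pleiotropic = sorted(pleio)
    truth.params.update(
        {"n_themes": n_themes, "n_pleiotropic": n_pleiotropic,
         "n_background_seeded": n_background_seeded,
         "theme_vocab_size": theme_vocab_size,
         "recommended_rank": recommended_rank,
         "query_terms": {t: words[0] for t, words in themes.items()}}
    )
    return corpus, truth


# --------------------------------------------------------------------------
# islet images


@dataclass
class PlantedIslet:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b, pixels
    rotation: float = 0.0  # radians
    beta_fraction: float = 0.7  # insulin-positive share of interior pixels
    foreground: int = 120  # planted stain intensity above background


def _ellipse_mask(
    shape: tuple[int, int], islet: PlantedIslet
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - islet.center[0]
    dc = cc - islet.center[1]
    ct, st = np.cos(islet.rotation), np.sin(islet.rotation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = islet.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def gen_islet_image(
    dims: tuple[int, int] = (192, 192),
    islets: Sequence[PlantedIslet] | None = None,
    bit_depth: int = 8,
    background: int = 10,
    noise_sd: float = 2.0,
    roi_margin: float = 1.4,
    seed: int = 0,
) -> tuple[ChannelImage, ChannelImage, list[IsletRoi], SyntheticTruth]:
    """Two-channel islet image: rotated filled ellipses split into an
    insulin-positive (beta) and glucagon-positive (alpha) interior partition
    at the planted fraction, over a uniform background offset with Gaussian
    pixel noise, clipped to the bit depth.

    One ROI per islet: the planted ellipse dilated by ``roi_margin``.
    """
    rng = np.random.default_rng(seed)
    if islets is None:
        islets = [PlantedIslet(center=(dims[0] / 2, dims[1] / 2), semi_axes=(40, 25))]
    maxval = 2**bit_depth - 1
    ins = np.zeros(dims, dtype=float)
    glu = np.zeros(dims, dtype=float)
    rois: list[IsletRoi] = []
    for islet in islets:
        mask = _ellipse_mask(dims, islet)
        coords = np.argwhere(mask)
        if coords.shape[0] == 0:
            raise ValueError("planted ellipse lies outside the image")
        # partition interior along the major axis: first beta_fraction of
        # pixels (by projected coordinate) are insulin-positive
        dr = coords[:, 0] - islet.center[0]
        dc = coords[:, 1] - islet.center[1]
        u = dr * np.cos(islet.rotation) + dc * np.sin(islet.rotation)
        order = np.argsort(u, kind="stable")
        n_beta = int(round(islet.beta_fraction * len(order)))
        beta_px = coords[order[:n_beta]]
        alpha_px = coords[order[n_beta:]]
        ins[beta_px[:, 0], beta_px[:, 1]] = islet.foreground
        glu[alpha_px[:, 0], alpha_px[:, 1]] = islet.foreground
        roi_islet = PlantedIslet(
            center=islet.center,
            semi_axes=(islet.semi_axes[0] * roi_margin, islet.semi_axes[1] * roi_margin),
            rotation=islet.rotation,
        )
        rois.append(IsletRoi(_ellipse_mask(dims, roi_islet)))

    images = []
    for arr in (ins, glu):
        noisy = arr + background + rng.normal(0.0, noise_sd, size=dims)
        images.append(
            ChannelImage(
                np.clip(np.floor(noisy + 0.5), 0, maxval).astype(np.int64),
                bit_depth,
            )
        )
    images[0].channel_label = "insulin"
    images[1].channel_label = "glucagon"
    truth = SyntheticTruth(
        seed=seed,
        generator="islets",
        params={
            "dims": list(dims), "bit_depth": bit_depth, "background": background,
            "noise_sd": noise_sd, "roi_margin": roi_margin,
        },
        planted_islets=[
            {
                "center": list(i.center), "semi_axes": list(i.semi_axes),
                "rotation": i.rotation, "beta_fraction": i.beta_fraction,
                "foreground": i.foreground,
            }
            for i in islets
        ],
    )
    return images[0], images[1], rois, truth


# --------------------------------------------------------------------------
# protein lists


def gen_protein_lists(
    n_a: int = 170,
    n_b: int = 153,
    overlap_fraction: float = 0.65,
    universe: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str], SyntheticTruth]:
    """Two identifier lists (e.g. co-precipitating protein sets from two
    conditions) with an exact planted overlap.

    ``overlap_fraction`` is the conserved fraction |A and B| / |A or B|; the
    overlap count is solved from it and the two list sizes.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    overlap = int(round(overlap_fraction * (n_a + n_b) / (1.0 + overlap_fraction)))
    overlap = min(overlap, n_a, n_b)
    union = n_a + n_b - overlap
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = [f"Prot{i:05d}" for i in range(max(2 * union, union + 10))]
    universe = list(universe)
    if len(universe) < union:
        raise ValueError("universe smaller than the required union")
    picked = rng.choice(len(universe), size=union, replace=False)
    ids = [universe[i] for i in picked]
    shared = ids[:overlap]
    a_only = ids[overlap : overlap + (n_a - overlap)]
    b_only = ids[overlap + (n_a - overlap) :]
    list_a = sorted(shared + a_only)
    list_b = sorted(shared + b_only)
    truth = SyntheticTruth(
        seed=seed,
        generator="proteins",
        params={"n_a": n_a, "n_b": n_b, "overlap_fraction": overlap_fraction},
        planted_overlap=overlap,
    )
    return list_a, list_b, truth
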