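"""Synthetic labeled scRNA-seq-like TPM matrices with planted phase markers.

The generator emulates a three-phase (G1 / S / G2M) single-cell design:
log-normal expression with a class-dependent location shift for marker
genes, Bernoulli dropout zeros, and per-cell TPM rescaling (each row sums
to 1e6 over the simulated gene universe). It provides ground truth for
every downstream stage: which genes carry phase information and which are
exchangeable noise.

The model deliberately omits library-size and gene-length effects,
negative-binomial counts, batch effects and pseudotime structure: the
downstream methods only require class-dependent location shifts against
exchangeable noise on a TPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "degenerate_case", "SEPARATOR_GENE"]

TPM_TOTAL = 1e6
SEPARATOR_GENE = "SEPARATOR"

#: class order of ``n_per_class``; sizes quoted per phase in this order.
CLASS_ORDER = ("G1", "G2M", "S")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic three-phase design.

    ``n_per_class`` is ordered (G1, G2M, S); the default sizes (346, 387,
    334) mirror a FUCCI-sorted U2OS single-cell atlas. ``effect_size`` is
    the mean log-expression shift of a marker gene in its own phase, in
    units of ``log_sd``. ``marker_direction`` is "up" (all markers
    up-regulated in their phase) or "symmetric" (alternating up/down
    shifts, for testing rule signs).
    """

    n_per_class: tuple[int, int, int] = (346, 387, 334)
    n_genes: int = 2000
    n_markers_per_class: int = 20
    effect_size: float = 2.0
    base_log_mean: float = 3.0
    log_sd: float = 1.0
    dropout_rate: float = 0.3
    seed: int = 0
    marker_direction: str = "up"

    def validate(self) -> None:
        if len(self.n_per_class) != 3 or any(int(n) <= 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be three positive integers")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_markers_per_class < 0:
            raise ValueError("n_markers_per_class must be non-negative")
        if 3 * self.n_markers_per_class > self.n_genes:
            raise ValueError("3 * n_markers_per_class must not exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.dropout_rate >= 1.0:
            raise ValueError("dropout_rate of 1 would zero every entry")
        if self.marker_direction not in {"up", "symmetric"}:
            raise ValueError("marker_direction must be 'up' or 'symmetric'")


@dataclass
class GroundTruth:
    """Which genes were planted as phase markers and which are noise.

    The three marker sets and the noise set are pairwise disjoint and
    their union is the full gene universe.
    """

    marker_sets: dict[str, set[str]]
    noise_genes: set[str] = field(default_factory=set)

    @property
    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.marker_sets.values():
            out |= s
        return out

    def validate(self, gene_ids: list[str]) -> None:
        sets = list(self.marker_sets.values()) + [self.noise_genes]
        union: set[str] = set()
        total = 0
        for s in sets:
            union |= s
            total += len(s)
        if total != len(union):
            raise ValueError("marker sets and noise genes are not pairwise disjoint")
        if union != set(gene_ids):
            raise ValueError("marker sets + noise genes do not cover the gene universe")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one labeled matrix from the generative model.

    For cell i in phase c and gene g: ``raw = exp(N(mu_gc, log_sd^2))``
    with ``mu_gc = base_log_mean + effect_size * log_sd`` when g is a
    marker of c (minus for down-shifted markers under "symmetric"), else
    ``base_log_mean``. Each entry is independently zeroed with probability
    ``dropout_rate``; rows left all-zero are redrawn; each row is rescaled
    to sum to 1e6. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gene_ids = _gene_ids(spec.n_genes)

    m = spec.n_markers_per_class
    marker_idx = rng.choice(spec.n_genes, size=3 * m, replace=False) if m else np.array([], int)
    marker_sets: dict[str, set[str]] = {}
    mu_shift = np.zeros((3, spec.n_genes))
    for ci, phase in enumerate(CLASS_ORDER):
        idx = marker_idx[ci * m : (ci + 1) * m]
        marker_sets[phase] = {gene_ids[j] for j in idx}
        for pos, j in enumerate(idx):
            sign = -1.0 if (spec.marker_direction == "symmetric" and pos % 2 == 1) else 1.0
            mu_shift[ci, j] = sign * spec.effect_size * spec.log_sd
    noise = set(gene_ids) - set().union(*marker_sets.values()) if m else set(gene_ids)
    truth = GroundTruth(marker_sets=marker_sets, noise_genes=noise)
    truth.validate(gene_ids)

    blocks = []
    labels = []
    for ci, phase in enumerate(CLASS_ORDER):
        n_c = int(spec.n_per_class[ci])
        mu = spec.base_log_mean + mu_shift[ci]
        block = _draw_block(rng, n_c, mu, spec.log_sd, spec.dropout_rate)
        blocks.append(block)
        labels.extend([phase] * n_c)
    values = np.vstack(blocks)
    values *= TPM_TOTAL / values.sum(axis=1, keepdims=True)
    em = ExpressionMatrix(values, gene_ids, [f"CELL{i:05d}" for i in range(len(labels))],
                          np.asarray(labels, dtype=object))
    return em, truth


def _draw_block(rng: np.random.Generator, n: int, mu: np.ndarray, sd: float,
                dropout: float) -> np.ndarray:
    block = np.exp(rng.normal(mu, sd, size=(n, mu.size)))
    if dropout > 0:
        block[rng.random(block.shape) < dropout] = 0.0
    # all-zero cells have undefined TPM: redraw them
    bad = np.flatnonzero(block.sum(axis=1) == 0)
    while bad.size:
        redraw = np.exp(rng.normal(mu, sd, size=(bad.size, mu.size)))
        if dropout > 0:
            redraw[rng.random(redraw.shape) < dropout] = 0.0
        block[bad] = redraw
        bad = bad[redraw.sum(axis=1) == 0]
    return block


def degenerate_case(kind: str, spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Boundary-condition datasets.

    ``pure-noise`` plants no markers at all (every gene uninformative).
    ``perfect-separation`` appends one extra gene, :data:`SEPARATOR_GENE`,
    whose pre-TPM value is a distinct constant per phase (exempt from
    dropout), so a single-gene decision tree separates the classes
    exactly; it is recorded among ``noise_genes`` since it belongs to no
    single phase's marker set.
    """
    spec.validate()
    if kind == "pure-noise":
        return generate(replace(spec, n_markers_per_class=0))
    if kind == "perfect-separation":
        em, truth = generate(spec)
        consts = {"G1": 1e2, "G2M": 1e4, "S": 1e6}
        # undo TPM scaling is unnecessary: append the constant column to the
        # raw-scale values reconstructed from row sums, then rescale again.
        col = np.array([consts[l] for l in em.labels], dtype=float)[:, None]
        values = np.hstack([em.values, col])
        values *= TPM_TOTAL / values.sum(axis=1, keepdims=True)
        em2 = ExpressionMatrix(values, em.gene_ids + [SEPARATOR_GENE], em.cell_ids, em.labels)
        truth.noise_genes = set(truth.noise_genes) | {SEPARATOR_GENE}
        truth.validate(em2.gene_ids)
        return em2, truth
    raise ValueError(f"unknown degenerate case: {kind!r}")
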