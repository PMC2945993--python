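"""Multi-level 2x2 Haar feature cascade over reaction images.

Each reaction image (expression painted onto the embedding grid) is tiled
into disjoint 2x2 blocks.  Per block four combined values are computed from
the row means m_u = (a+b)/2, m_l = (c+d)/2 and row differences d_u = a-b,
d_l = c-d:

    f1 = (m_u + m_l)/2   mean of means       (low pass)
    f2 =  m_u - m_l      difference of means
    f3 = (d_u + d_l)/2   mean of differences
    f4 =  d_u - d_l      difference of differences (high pass)

The f1 values form the next level's matrix and the blocking recurses until
a single block remains; odd dimensions are zero-padded on the bottom/right.
"Mean" here is a plain average and "difference" a plain difference — no
orthonormal sqrt(2) scaling.  Downstream testing is rank-based, so any fixed
positive rescaling of a coefficient leaves its p-value unchanged.

Because empty grid cells are zero-filled, whether a feature is informative
is decided structurally: a feature is non-trivial when its spatial footprint
contains at least one reaction-bearing cell and its value varies across
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureDescriptor",
    "FeatureTable",
    "pad_matrix",
    "haar_block",
    "reconstruct_block",
    "cascade",
    "enumerate_nontrivial",
    "ALL_OFFSETS",
]

ALL_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identifies one wavelet coefficient: where and what it combines."""

    pathway_id: str
    level: int
    block: tuple[int, int]
    offset: tuple[int, int]
    coeff_type: int
    support: frozenset[str]


@dataclass
class FeatureTable:
    """Wavelet features (rows) by samples (columns)."""

    descriptors: list[FeatureDescriptor]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.descriptors), len(self.sample_ids)):
            raise ValueError("values shape must be (n_features, n_samples)")

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if self.sample_ids != other.sample_ids:
            raise ValueError("sample order mismatch")
        return FeatureTable(
            self.descriptors + other.descriptors,
            np.vstack([self.values, other.values]) if self.n_features and other.n_features
            else (other.values if not self.n_features else self.values),
            self.sample_ids,
        )


def pad_matrix(matrix: np.ndarray) -> np.ndarray:
    """Append zero rows/columns on the bottom/right until dimensions are even."""
    m = np.asarray(matrix, dtype=float)
    pr = m.shape[-2] % 2
    pc = m.shape[-1] % 2
    if not pr and not pc:
        return m
    pad = [(0, 0)] * (m.ndim - 2) + [(0, pr), (0, pc)]
    return np.pad(m, pad)


def haar_block(block) -> tuple[float, float, float, float]:
    """Four combined values of one 2x2 block ((a, b), (c, d))."""
    (a, b), (c, d) = np.asarray(block, dtype=float)
    m_u, m_l = (a + b) / 2, (c + d) / 2
    d_u, d_l = a - b, c - d
    return ((m_u + m_l) / 2, m_u - m_l, (d_u + d_l) / 2, d_u - d_l)


def reconstruct_block(f1: float, f2: float, f3: float, f4: float) -> np.ndarray:
    """Invert :func:`haar_block`, returning the 2x2 block."""
    m_u, m_l = f1 + f2 / 2, f1 - f2 / 2
    d_u, d_l = f3 + f4 / 2, f3 - f4 / 2
    return np.array([[m_u + d_u / 2, m_u - d_u / 2], [m_l + d_l / 2, m_l - d_l / 2]])


def _pad_support(sup: np.ndarray) -> np.ndarray:
    pr = sup.shape[0] % 2
    pc = sup.shape[1] % 2
    if not pr and not pc:
        return sup
    out = np.full((sup.shape[0] + pr, sup.shape[1] + pc), None, dtype=object)
    for idx in np.ndindex(out.shape):
        out[idx] = frozenset()
    out[: sup.shape[0], : sup.shape[1]] = sup
    return out


def _support_grid(placement: dict[str, tuple[int, int]], side: int) -> np.ndarray:
    sup = np.full((side, side), None, dtype=object)
    for idx in np.ndindex(sup.shape):
        sup[idx] = frozenset()
    for rid, (i, j) in placement.items():
        sup[i, j] = frozenset([rid])
    return sup


def cascade(
    images: np.ndarray,
    placement: dict[str, tuple[int, int]],
    pathway_id: str,
    sample_ids: list[str],
    offsets_mode: str = "all4",
) -> FeatureTable:
    """Full Haar cascade over a stack of reaction images.

    Parameters
    ----------
    images
        Array of shape (n_samples, side, side): one reaction image per
        sample, all on the same embedding.
    placement
        reaction_id -> (i, j), defining the support of each cell.
    offsets_mode
        ``"single"`` tiles from origin (0, 0) only; ``"all4"`` repeats the
        cascade for the four shift origins, covering every arrangement of
        2x2 blocks over the grid.
    """
    if offsets_mode not in ("single", "all4"):
        raise ValueError("offsets_mode must be 'single' or 'all4'")
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError("images must be (n_samples, side, side)")
    side = images.shape[1]
    base_sup = _support_grid(placement, side)
    offsets = ALL_OFFSETS if offsets_mode == "all4" else ((0, 0),)

    descriptors: list[FeatureDescriptor] = []
    rows: list[np.ndarray] = []
    for dy, dx in offsets:
        cur = np.pad(images, [(0, 0), (dy, 0), (dx, 0)])
        sup = np.full((side + dy, side + dx), None, dtype=object)
        for idx in np.ndindex(sup.shape):
            sup[idx] = frozenset()
        sup[dy:, dx:] = base_sup

        level = 0
        while True:
            cur = pad_matrix(cur)
            sup = _pad_support(sup)
            a = cur[:, 0::2, 0::2]
            b = cur[:, 0::2, 1::2]
            c = cur[:, 1::2, 0::2]
            d = cur[:, 1::2, 1::2]
            m_u, m_l = (a + b) / 2, (c + d) / 2
            d_u, d_l = a - b, c - d
            coeffs = ((m_u + m_l) / 2, m_u - m_l, (d_u + d_l) / 2, d_u - d_l)
            nbr, nbc = a.shape[1], a.shape[2]
            for br in range(nbr):
                for bc in range(nbc):
                    block_sup = (
                        sup[2 * br, 2 * bc]
                        | sup[2 * br, 2 * bc + 1]
                        | sup[2 * br + 1, 2 * bc]
                        | sup[2 * br + 1, 2 * bc + 1]
                    )
                    for ct in range(4):
                        descriptors.append(
                            FeatureDescriptor(
                                pathway_id, level, (br, bc), (dy, dx), ct + 1, block_sup
                            )
                        )
                        rows.append(coeffs[ct][:, br, bc])
            if nbr == 1 and nbc == 1:
                break
            cur = coeffs[0]
            new_sup = np.full((nbr, nbc), None, dtype=object)
            for br in range(nbr):
                for bc in range(nbc):
                    new_sup[br, bc] = (
                        sup[2 * br, 2 * bc]
                        | sup[2 * br, 2 * bc + 1]
                        | sup[2 * br + 1, 2 * bc]
                        | sup[2 * br + 1, 2 * bc + 1]
                    )
            sup = new_sup
            level += 1

    values = np.array(rows) if rows else np.empty((0, images.shape[0]))
    return FeatureTable(descriptors, values, list(sample_ids))


def enumerate_nontrivial(table: FeatureTable, atol: float = 1e-12) -> FeatureTable:
    """Keep features supported by >= 1 reaction and varying across samples."""
    keep = [
        k
        for k, desc in enumerate(table.descriptors)
        if desc.support and np.ptp(table.values[k]) > atol
    ]
    return FeatureTable(
        [table.descriptors[k] for k in keep], table.values[keep], table.sample_ids
    )
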