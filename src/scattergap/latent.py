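"""Latent-space quality analysis of inpainting.

The downstream value of inpainting is probed by embedding three aligned
image sets - masked, ground truth and inpainted - with identically
configured and identically seeded reconstruction autoencoders, then asking
whether the neighborhood structure of the ground-truth embedding survives:
(i) the mean Pearson correlation between each image and its rank-r latent
neighbor (computed on the masked pixel vectors for every space, so gap
zeros offset all spaces equally) as a function of r, and (ii) the overlap
of each image's 100 nearest neighbors between a query space and the
ground-truth reference space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv2d, ConvTranspose2x2, Linear, Module, Tensor
from .nn import functional as F

__all__ = [
    "LatentSpace",
    "EmbeddingAutoencoder",
    "train_embedding",
    "neighbor_rank_curve",
    "knn_overlap",
]

LATENT_DIM = 200


@dataclass(frozen=True)
class LatentSpace:
    """An ``N x dim`` embedding matrix aligned with image identifiers."""

    vectors: np.ndarray
    image_ids: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        ids = np.asarray(self.image_ids)
        if v.ndim != 2:
            raise ValueError("vectors must be N x dim")
        if ids.shape != (v.shape[0],):
            raise ValueError("one id per vector required")
        if not np.isfinite(v).all():
            raise ValueError("latent vectors must be finite")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "image_ids", ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class EmbeddingAutoencoder(Module):
    """Small convolutional autoencoder with a dense 200-D bottleneck.

    Encoder: conv + ReLU + 2x2 max-pool stages, global mean pooling, then a
    dense projection to the latent dimension.  Decoder: dense expansion to
    a coarse spatial map followed by transposed-conv upsampling back to the
    input size; trained with the L1 reconstruction loss.  This is a
    deliberately separate, simpler network from the inpainting autoencoder:
    its only job is to define a latent geometry, identically for each image
    set.
    """

    def __init__(
        self,
        image_size: tuple[int, int],
        dim: int = LATENT_DIM,
        channels: tuple[int, ...] = (8, 16, 16),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        H, W = image_size
        f = 2 ** len(channels)
        if H % f or W % f:
            raise ValueError(f"image size {H}x{W} must be divisible by {f}")
        self.image_size = image_size
        self.dim = dim
        self.enc = []
        c_in = 1
        for c in channels:
            self.enc.append(Conv2d(c_in, c, 3, rng))
            c_in = c
        self.to_latent = Linear(c_in, dim, rng)
        h, w = H // f, W // f
        self._coarse = (channels[-1], h, w)
        self.from_latent = Linear(dim, channels[-1] * h * w, rng)
        self.dec = []
        rev = list(channels[::-1][1:]) + [channels[0]]
        c_in = channels[-1]
        for c in rev:
            self.dec.append(ConvTranspose2x2(c_in, c, rng))
            c_in = c
        self.head = Conv2d(c_in, 1, 1, rng)

    def encode(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.enc:
            h = F.maxpool2x2(F.relu(conv(h)))
        return self.to_latent(F.global_mean_pool(h))

    def __call__(self, x: Tensor) -> Tensor:
        z = self.encode(x)
        c, hh, ww = self._coarse
        h = F.relu(self.from_latent(z))
        h = F.reshape(h, (x.data.shape[0], c, hh, ww))
        for up in self.dec:
            h = F.relu(up(h))
        return self.head(h)

    def embed(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Encode a stack of frames to ``(N, dim)`` latent vectors."""
        images = np.asarray(images, dtype=np.float32)
        out = []
        for start in range(0, len(images), batch_size):
            x = Tensor(images[start : start + batch_size, None])
            out.append(self.encode(x).data)
        return np.concatenate(out, axis=0).astype(np.float64)


def train_embedding(
    images: np.ndarray,
    dim: int = LATENT_DIM,
    epochs: int = 5,
    batch_size: int = 8,
    lr: float = 1e-3,
    seed: int = 0,
) -> EmbeddingAutoencoder:
    """Reconstruction-train an embedding autoencoder on an image stack.

    Comparing latent spaces across image sets is only meaningful when every
    call uses identical settings and the identical seed; the builder's
    weight initialization and the batch order depend on ``seed`` alone.
    ``epochs=0`` returns the reproducible randomly initialized encoder.
    """
    if dim != LATENT_DIM:
        import warnings

        warnings.warn(
            f"latent dimension {dim} differs from the reference setting "
            f"{LATENT_DIM}; results are not comparable with the standard protocol",
            stacklevel=2,
        )
    images = np.asarray(images, dtype=np.float32)
    net = EmbeddingAutoencoder(images.shape[1:], dim=dim, seed=seed)
    if epochs == 0:
        return net
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=lr)
    order = np.arange(len(images))
    for _ in range(epochs):
        rng.shuffle(order)
        for start in range(0, len(order), batch_size):
            x = images[order[start : start + batch_size], None]
            out = net(Tensor(x))
            loss = F.l1_loss(out, x)
            net.zero_grad()
            loss.backward()
            opt.step()
    return net


def _neighbor_order(space: LatentSpace) -> np.ndarray:
    """All-pairs neighbor ordering: ascending distance, ties by image id,
    self excluded; returns (N, N-1) index matrix into the space."""
    v = space.vectors
    n = v.shape[0]
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)
    order = np.empty((n, n - 1), dtype=np.int64)
    ids = space.image_ids
    for i in range(n):
        cand = np.delete(np.arange(n), i)
        key_d = d2[i, cand]
        o = np.lexsort((ids[cand], key_d))
        order[i] = cand[o]
    return order


def neighbor_rank_curve(
    space: LatentSpace, masked_images: np.ndarray, max_rank: int
) -> np.ndarray:
    """Mean image-to-neighbor Pearson correlation at each neighbor rank.

    Rank 1 is the nearest *other* image by Euclidean latent distance.  The
    correlations are computed between flattened masked pixel vectors (the
    same masked set for every latent space under comparison, so constant
    gap zeros offset all spaces identically).
    """
    n = space.vectors.shape[0]
    if not 1 <= max_rank < n:
        raise ValueError(f"max_rank must lie in [1, {n - 1}]")
    masked_images = np.asarray(masked_images, dtype=np.float64)
    if masked_images.shape[0] != n:
        raise ValueError("one masked image per latent vector required")
    flat = masked_images.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(flat, axis=1)
    norm[norm == 0] = 1.0
    flat = flat / norm[:, None]
    order = _neighbor_order(space)
    curve = np.empty(max_rank, dtype=np.float64)
    for r in range(1, max_rank + 1):
        nb = order[:, r - 1]
        curve[r - 1] = float((flat * flat[nb]).sum(axis=1).mean())
    return curve


def knn_overlap(space_ref: LatentSpace, space_query: LatentSpace, k: int = 100) -> np.ndarray:
    """Percentage overlap of each image's k nearest neighbors.

    Neighbor sets (self excluded) are taken in the reference space -
    canonically the ground-truth embedding - and in the query space; the
    per-image score is ``|intersection(kNN_ref, kNN_query)| / k * 100``.
    """
    if space_ref.vectors.shape[0] != space_query.vectors.shape[0] or not np.array_equal(
        space_ref.image_ids, space_query.image_ids
    ):
        raise ValueError("latent spaces must be aligned on the same image ids")
    n = space_ref.vectors.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must lie in [1, {n - 1}]")
    ref = _neighbor_order(space_ref)[:, :k]
    qry = _neighbor_order(space_query)[:, :k]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = len(set(ref[i]) & set(qry[i])) / k * 100.0
    return out
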