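"""Seeded synthetic expression data with planted ground truth.

The generator emulates the hierarchical structure the ranking model
assumes: every gene's baseline mean is drawn from Normal(mu0, tau2) and
observations add Normal(0, sigma2) noise. Class-specific differential
genes shift their class's samples by a chosen effect (in units of the
noise sd sigma, alternating up/down). Each class additionally carries one
co-regulated gene block driven by a shared latent factor (pairwise
correlation >= 0.9) placed among its up-regulated planted genes, and one
non-differential gene pair with a purely quadratic (zero linear
correlation) dependency, so both network estimators have a planted target.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ExpressionDataset, MarkernetError, derive_rng

# latent-factor loading, in sigma units; after within-class centering the
# implied pairwise correlation is l^2*(1-1/n)/(l^2*(1-1/n)+1) ~ 0.95
_BLOCK_LOADING = 4.5


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    de_genes: dict[str, dict[str, float]]  # class -> gene -> signed effect (sigma units)
    blocks: dict[str, list[str]]  # class -> co-regulated block genes
    quadratic_pairs: dict[str, tuple[str, str]]  # class -> (driver, response)
    params: dict

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "blocks": self.blocks,
            "quadratic_pairs": {
                k: list(v) for k, v in self.quadratic_pairs.items()
            },
            "params": self.params,
        }


def generate(
    n_classes: int = 5,
    n_per_class: int = 12,
    n_genes: int = 2000,
    de_per_class: int = 50,
    effect: float = 4.0,
    block_size: int = 5,
    mu0: float = 7.0,
    tau2: float = 4.0,
    sigma2: float = 0.25,
    seed: int = 0,
    class_names=None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a labelled genes x samples matrix with planted structure.

    Effects are in units of sigma (the noise sd) so recovery thresholds are
    scale-free. Planted gene sets are disjoint across classes; the same
    seed always reproduces the identical matrix.
    """
    de_counts = (
        [int(de_per_class)] * n_classes
        if np.isscalar(de_per_class)
        else [int(v) for v in de_per_class]
    )
    if len(de_counts) != n_classes:
        raise MarkernetError("de_per_class sequence must have one entry per class")
    if sum(de_counts) > n_genes:
        raise MarkernetError("total de_per_class exceeds n_genes")
    if effect < 0:
        raise MarkernetError("effect must be >= 0")
    if n_classes < 2 or n_per_class < 3:
        raise MarkernetError("need >= 2 classes and >= 3 samples per class")
    rng = derive_rng(seed, "synthetic")
    sigma = float(np.sqrt(sigma2))
    classes = (
        list(class_names)
        if class_names is not None
        else [f"C{k+1}" for k in range(n_classes)]
    )
    if len(classes) != n_classes:
        raise MarkernetError("class_names length must equal n_classes")

    gene_ids = [f"g{j+1:05d}" for j in range(n_genes)]
    sample_ids = [
        f"{c}_s{i+1:02d}" for c in classes for i in range(n_per_class)
    ]
    labels = {s: s.rsplit("_s", 1)[0] for s in sample_ids}
    y = np.repeat(np.arange(n_classes), n_per_class)
    n_samples = n_classes * n_per_class

    base = rng.normal(mu0, np.sqrt(tau2), size=n_genes)
    M = base[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_samples))

    de: dict[str, dict[str, float]] = {c: {} for c in classes}
    blocks: dict[str, list[str]] = {}
    quad: dict[str, tuple[str, str]] = {}
    cursor = 0
    for k, c in enumerate(classes):
        idx = np.arange(cursor, cursor + de_counts[k])
        cursor += de_counts[k]
        in_class = y == k
        for pos, gi in enumerate(idx):
            sign = 1.0 if pos % 2 == 0 else -1.0  # alternate UP/DOWN
            M[gi, in_class] += sign * effect * sigma
            de[c][gene_ids[gi]] = sign * effect
        # co-regulated block among the class's UP genes (even positions)
        up_idx = idx[::2][: max(block_size, 0)]
        if block_size > 0 and len(up_idx) >= block_size:
            bidx = up_idx[:block_size]
            z = rng.normal(0.0, 1.0, size=n_samples)
            # center the latent factor within every class so co-expression
            # perturbs residuals, not the between-class signal
            for k2 in range(n_classes):
                m2 = y == k2
                z[m2] -= z[m2].mean()
            M[bidx] += _BLOCK_LOADING * sigma * z[None, :]
            blocks[c] = [gene_ids[g] for g in bidx]

    # one quadratic (zero-linear-correlation) pair per class, in non-DE genes
    for k, c in enumerate(classes):
        if cursor + 2 > n_genes:
            break
        a, b = cursor, cursor + 1
        cursor += 2
        u = rng.normal(0.0, 1.0, size=n_samples)
        M[a] = base[a] + sigma * u
        M[b] = base[b] + sigma * (u**2 - 1.0) / np.sqrt(2.0)
        quad[c] = (gene_ids[a], gene_ids[b])

    matrix = pd.DataFrame(M, index=gene_ids, columns=sample_ids)
    dataset = ExpressionDataset(matrix, labels)
    truth = SyntheticTruth(
        de_genes=de,
        blocks=blocks,
        quadratic_pairs=quad,
        params={
            "n_classes": n_classes,
            "n_per_class": n_per_class,
            "n_genes": n_genes,
            "de_per_class": de_per_class,
            "effect": effect,
            "block_size": block_size,
            "mu0": mu0,
            "tau2": tau2,
            "sigma2": sigma2,
            "seed": seed,
        },
    )
    return dataset, truth


def separable_dataset(
    n_classes: int = 5,
    n_per_class: int = 12,
    n_genes: int = 2000,
    de_per_class: int = 50,
    seed: int = 0,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Planted dataset in the fully separable regime.

    Class-specific effects of 10 sigma give each class-conditional marker
    distribution a disjoint 5-sigma envelope, so held-out samples are
    unambiguous; no co-regulated blocks perturb the markers. This is the
    reference condition for end-to-end classification experiments, whereas
    :func:`generate`'s 4-sigma default is the harder regime used for
    ranking-recovery experiments.
    """
    return generate(
        n_classes=n_classes,
        n_per_class=n_per_class,
        n_genes=n_genes,
        de_per_class=de_per_class,
        effect=10.0,
        block_size=0,
        seed=seed,
    )


def generate_rnaseq_like(
    rpkm_scale: float = 20.0, **kwargs
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """RNA-Seq-flavoured variant: log-normal RPKM, then log2(RPKM+1).

    The log2(RPKM+1) matrix keeps the same planted log-scale structure as
    :func:`generate` (the generated values are treated as log2(RPKM+1)
    directly after shifting to a positive range); an ``rpkm`` frame of raw
    nonnegative values is recoverable as 2**x - 1.
    """
    ds, truth = generate(**kwargs)
    # shift in log2 space so the median RPKM is near rpkm_scale and every
    # value stays nonnegative; a pure shift preserves the planted structure
    m = ds.matrix.to_numpy()
    shift = max(
        float(np.log2(rpkm_scale) - np.median(m)), -float(m.min()) + 0.01
    )
    scaled = m + shift
    rpkm = np.power(2.0, scaled) - 1.0
    if (rpkm < 0).any():
        raise MarkernetError("internal error: negative RPKM generated")
    logged = np.log2(rpkm + 1.0)
    matrix = pd.DataFrame(logged, index=ds.gene_ids, columns=ds.sample_ids)
    truth.params["rpkm_scale"] = rpkm_scale
    truth.params["shift"] = shift
    return ExpressionDataset(matrix, dict(ds.labels)), truth


def pure_noise_queries(
    dataset: ExpressionDataset,
    n_queries: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Samples x genes queries drawn from the null (no class signal).

    Each query gene value is the dataset's overall gene mean plus noise at
    the dataset's pooled within-class sd, so queries resemble the training
    scale but carry no class structure.
    """
    rng = derive_rng(seed, "noise-queries")
    means = dataset.matrix.to_numpy().mean(axis=1)
    X, ylab = dataset.to_xy()
    resid = []
    for c in dataset.classes:
        sub = X.to_numpy()[ylab == c]
        resid.append(sub - sub.mean(axis=0))
    sd = np.concatenate(resid, axis=0).std(axis=0, ddof=1)
    Q = means[None, :] + rng.normal(0.0, sd, size=(n_queries, len(means)))
    return pd.DataFrame(
        Q, columns=dataset.gene_ids,
        index=[f"noise_{i+1:03d}" for i in range(n_queries)],
    )
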