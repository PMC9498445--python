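"""End-to-end assembly: features -> kernels -> integrated Sm / St -> fit.

The static kernels (free energy, sequence, SSR, accessibility, AU) depend
only on the sequences and are computed once; the two Gaussian
interaction-profile kernels (miRNA rows, site columns) depend on the
adjacency matrix and are rebuilt from whatever (possibly masked) training
matrix the caller supplies, which is what keeps cross-validation
leakage-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import Config
from .data_model import Dataset, Role, SequenceRecord, trim_site
from .features import FeatureTable, FoldingProvider, NussinovProvider, feature_table
from .kernels import (
    SimilarityKernel,
    gaussian_profile_kernel,
    integrate_kernels,
    nearest_psd,
    nw_similarity_kernel,
    scalar_gaussian_kernel,
)
from .rls import RLSModel, fit

__all__ = ["StaticKernels", "prepare_dataset", "build_static_kernels",
           "gp_kernels", "mirna_kernel", "site_kernel", "integrated_kernels",
           "fit_dataset"]


@dataclass
class StaticKernels:
    """Adjacency-independent kernels plus the feature tables behind them."""

    mirna: dict[str, SimilarityKernel]  # keys: FE, NW, SSR
    site: dict[str, SimilarityKernel]   # keys: FE, TA, AU, SSR
    mirna_features: FeatureTable
    site_features: FeatureTable


def prepare_dataset(dataset: Dataset, config: Config | None = None) -> Dataset:
    """Trim target sites to the configured length (miRNAs untouched)."""
    config = config or Config()
    sites = [
        SequenceRecord(r.id, Role.TARGET_SITE,
                       trim_site(r.sequence, config.site_length),
                       r.source_transcript)
        for r in dataset.sites
    ]
    return Dataset(dataset.mirnas, sites, dataset.interactions, dict(dataset.meta))


def _profile_kernel(vectors: np.ndarray, ids: list[str], phi_prime: float,
                    kind: str) -> SimilarityKernel:
    """Profile kernel with an all-ones fallback for all-zero profiles.

    If every profile vector is zero the entities are indistinguishable on
    this feature and the kernel is the all-ones matrix (which is what the
    Gaussian form gives for identical vectors at any bandwidth).
    """
    V = np.asarray(vectors, dtype=float)
    if not V.any():
        warnings.warn(
            f"{kind} kernel: all profile vectors are zero; using the "
            "all-ones kernel (entities indistinguishable on this feature)",
            stacklevel=2,
        )
        n = V.shape[0]
        return SimilarityKernel(list(ids), np.ones((n, n)), kind)
    return gaussian_profile_kernel(V, ids, phi_prime=phi_prime, kind=kind)


def build_static_kernels(dataset: Dataset, config: Config | None = None,
                         provider: FoldingProvider | None = None) -> StaticKernels:
    """Compute every kernel that does not depend on the adjacency matrix."""
    config = config or Config()
    provider = provider or NussinovProvider()
    mids = [r.id for r in dataset.mirnas]
    tids = [r.id for r in dataset.sites]
    mf = feature_table(mids, dataset.mirna_sequences, provider,
                       min_repeats=config.ssr_min_repeats)
    tf = feature_table(tids, dataset.site_sequences, provider,
                       with_accessibility=True,
                       accessibility_window=config.accessibility_window,
                       min_repeats=config.ssr_min_repeats)
    mirna = {
        "FE": scalar_gaussian_kernel(mf.mfe, mids, config.phi_prime, kind="FE"),
        "NW": nw_similarity_kernel(dataset.mirna_sequences, mids,
                                   config.nw_match, config.nw_mismatch,
                                   config.nw_gap),
        "SSR": _profile_kernel(mf.ssr_matrix(config.ssr_binary), mids,
                               config.phi_prime, "SSR"),
    }
    site = {
        "FE": scalar_gaussian_kernel(tf.mfe, tids, config.phi_prime, kind="FE"),
        "TA": scalar_gaussian_kernel(tf.accessibility, tids, config.phi_prime,
                                     kind="TA"),
        "AU": scalar_gaussian_kernel(tf.au_fraction, tids, config.phi_prime,
                                     kind="AU"),
        "SSR": _profile_kernel(tf.ssr_matrix(config.ssr_binary), tids,
                               config.phi_prime, "SSR"),
    }
    return StaticKernels(mirna, site, mf, tf)


def gp_kernels(Y: np.ndarray, mirna_ids: list[str], site_ids: list[str],
               phi_prime: float = 1.0) -> tuple[SimilarityKernel, SimilarityKernel]:
    """Gaussian interaction-profile kernels from a training adjacency.

    Row profiles give the miRNA kernel, column profiles the site kernel.
    Only the miRNA GP kernel enters the integrated Sm; the column-profile
    kernel is provided for inspection.  Always build these from the
    TRAINING matrix (held-out cells zeroed).
    """
    Yf = np.asarray(Y, dtype=float)
    GPm = _profile_kernel(Yf, mirna_ids, phi_prime, "GP")
    GPt = _profile_kernel(Yf.T, site_ids, phi_prime, "GP")
    return GPm, GPt


def site_kernel(static: StaticKernels, Y: np.ndarray,
                config: Config | None = None) -> SimilarityKernel:
    """Integrated St = weighted average of (FE, TA, AU, SSR, GP) site kernels.

    The fifth component is the Gaussian interaction-profile kernel on the
    site columns of the training adjacency: it is what carries the
    "similar sites are bound by the same miRNAs" half of the model's
    assumption (a zero fifth weight removes it, leaving the strict
    feature-only site integration).  St is a convex combination of
    Gaussian kernels, hence PSD by construction -- no projection needed.
    """
    config = config or Config()
    tids = static.site["FE"].entity_ids
    GPt = _profile_kernel(np.asarray(Y, dtype=float).T, tids,
                          config.phi_prime, "GP")
    return integrate_kernels(
        [static.site["FE"], static.site["TA"], static.site["AU"],
         static.site["SSR"], GPt],
        config.site_weights, kind="St",
    )


def mirna_kernel(static: StaticKernels, Y: np.ndarray,
                 config: Config | None = None) -> SimilarityKernel:
    """Integrated Sm = weighted average of (FE, GP, NW, SSR) miRNA kernels.

    The GP component is rebuilt from the supplied training adjacency;
    the result is passed through the PSD projection because the clipped
    Needleman-Wunsch component can be indefinite.
    """
    config = config or Config()
    mids = static.mirna["FE"].entity_ids
    Yf = np.asarray(Y, dtype=float)
    GPm = _profile_kernel(Yf, mids, config.phi_prime, "GP")
    Sm = integrate_kernels(
        [static.mirna["FE"], GPm, static.mirna["NW"], static.mirna["SSR"]],
        config.mirna_weights, kind="Sm",
    )
    return nearest_psd(Sm)


def integrated_kernels(static: StaticKernels, Y: np.ndarray,
                       config: Config | None = None
                       ) -> tuple[SimilarityKernel, SimilarityKernel]:
    """Integrated (Sm, St) for a given training adjacency."""
    config = config or Config()
    return mirna_kernel(static, Y, config), site_kernel(static, Y, config)


def fit_dataset(dataset: Dataset, config: Config | None = None,
                provider: FoldingProvider | None = None,
                static: StaticKernels | None = None,
                Y_train: np.ndarray | None = None) -> RLSModel:
    """Fit the Kron-RLS model on a dataset (convenience wrapper)."""
    config = config or Config()
    dataset = prepare_dataset(dataset, config)
    if static is None:
        static = build_static_kernels(dataset, config, provider)
    Y = dataset.interactions.A if Y_train is None else np.asarray(Y_train)
    Sm, St = integrated_kernels(static, Y, config)
    return fit(Sm, St, Y.astype(float), config.lam)
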