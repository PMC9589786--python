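"""End-to-end feature extraction: signal -> surface -> mesh -> signature."""

from __future__ import annotations

import numpy as np

from .classify import FeatureTable, mfcc_feature_names, mfcc_features
from .distortion import FEATURE_NAMES, DistortionSignature, extract_signature
from .flattening import FlattenConfig
from .meshing import build_mesh
from .preprocess import (
    SGConfig,
    Signal,
    StftParams,
    compute_surface,
    modwt_denoise,
    savitzky_golay,
)

__all__ = ["signature_for_signal", "signature_table", "mfcc_table"]


def signature_for_signal(
    signal: Signal,
    kind: str = "stft",
    grid_n: int = 64,
    alpha: float = 1.0,
    denoise: str | None = None,
    sg_cfg: SGConfig = SGConfig(),
    stft_params: StftParams = StftParams(),
    flatten_cfg: FlattenConfig = FlattenConfig(),
) -> DistortionSignature:
    """Distortion signature of one recording.

    ``denoise`` selects the conditioning stage: ``'sg'`` (Savitzky-Golay,
    lung-type signals), ``'modwt'`` (wavelet thresholding, speech-type
    signals) or None.
    """
    if denoise == "sg":
        signal = savitzky_golay(signal, sg_cfg)
    elif denoise == "modwt":
        signal = modwt_denoise(signal)
    elif denoise is not None:
        raise ValueError(f"unknown denoise stage {denoise!r}; use 'sg' or 'modwt'")
    surface = compute_surface(
        signal, kind=kind, stft_params=stft_params, grid_n=grid_n, alpha=alpha
    )
    mesh = build_mesh(surface)
    return extract_signature(mesh, cfg=flatten_cfg)


def signature_table(
    signals: list[Signal], labels: list[str], groups: list[str] | None = None, **kwargs
) -> FeatureTable:
    """16-feature distortion table for a set of recordings."""
    rows = [signature_for_signal(s, **kwargs).values for s in signals]
    return FeatureTable.from_arrays(
        ids=[s.id for s in signals],
        groups=groups if groups is not None else [s.group for s in signals],
        labels=labels,
        X=np.asarray(rows),
        feature_names=list(FEATURE_NAMES),
    )


def mfcc_table(
    signals: list[Signal], labels: list[str], groups: list[str] | None = None,
    n_mfcc: int = 12,
) -> FeatureTable:
    """72-feature MFCC-statistics table for a set of recordings."""
    rows = [mfcc_features(s, n_mfcc=n_mfcc) for s in signals]
    return FeatureTable.from_arrays(
        ids=[s.id for s in signals],
        groups=groups if groups is not None else [s.group for s in signals],
        labels=labels,
        X=np.asarray(rows),
        feature_names=mfcc_feature_names(n_mfcc),
    )
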