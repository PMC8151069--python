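"""Closed-form integrals used by the Sturm-Liouville projections.

All integrals run over the log-radial interval [0, W] against sin(k x); the
exp(-3x/2) eigenfunction envelope cancels the exp(3x) weight so projections
reduce to plain integrals of the lifted profiles times exp(3x/2) or 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["int_exp_sin", "int_xexp_sin", "int_sinh_sin_scaled"]


def int_exp_sin(b: float, k: np.ndarray, W: float) -> np.ndarray:
    """``int_0^W exp(b x) sin(k x) dx`` (vectorised over k)."""
    nu = k * W
    return (np.exp(b * W) * (b * np.sin(nu) - k * np.cos(nu)) + k) / (b * b + k * k)


def int_xexp_sin(b: float, k: np.ndarray, W: float) -> np.ndarray:
    """``int_0^W x exp(b x) sin(k x) dx`` (vectorised over k)."""
    nu = k * W
    D = b * b + k * k
    ebw = np.exp(b * W)
    t1 = W * ebw * (b * np.sin(nu) - k * np.cos(nu)) / D
    e_cos = (ebw * (b * np.cos(nu) + k * np.sin(nu)) - b) / D
    return t1 - (b * int_exp_sin(b, k, W) - k * e_cos) / D


def int_sinh_sin_scaled(eta: np.ndarray, k: np.ndarray, W: float) -> np.ndarray:
    """``int_0^W sinh(eta x) sin(k x) dx / cosh(eta W)``, outer-product shape.

    Dividing by cosh(eta W) keeps the expression finite for large eta*W
    (tanh saturates); callers combine it with lifting amplitudes that carry
    the matching 1/cosh growth.  Returns an array of shape (len(k), len(eta)).
    """
    eta = np.atleast_1d(eta)[None, :]
    kk = np.atleast_1d(k)[:, None]
    nu = kk * W
    th = np.tanh(eta * W)
    return (eta * np.sin(nu) - kk * th * np.cos(nu)) / (eta * eta + kk * kk)
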