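"""Poincaré-ball operations at curvature −1/K.

Points live strictly inside the ball of radius √K; with c = 1/K the ball is
{x : √c‖x‖ < 1}.  The exponential/logarithmic maps are taken at the origin o,
and Möbius addition/matrix-multiplication provide the hyperbolic analogues of
vector-space operations.  All functions act on the last axis and accept plain
NumPy arrays or autodiff Tensors interchangeably (see :mod:`biohan.autodiff`).

Numerical safety: points are re-projected to norm ≤ (1−1e−5)·√K after every
operation, and artanh arguments are clamped to 1−1e−7.
"""

from __future__ import annotations

import math

from . import autodiff as ad

BOUNDARY_EPS = 1e-5
ATANH_EPS = 1e-7


def _sqrt_k(curvature_k):
    """√K, differentiable when the curvature itself is a trainable Tensor."""
    if isinstance(curvature_k, ad.Tensor):
        return ad.sqrt(curvature_k)
    return math.sqrt(curvature_k)


def project(x, curvature_k):
    """Clip a point to lie strictly inside the ball of curvature −1/K."""
    max_norm = (1.0 - BOUNDARY_EPS) * _sqrt_k(curvature_k)
    n = ad.norm(x)
    factor = ad.clamp(max_norm / n, max_value=1.0)
    return x * factor


def expmap0(v, curvature_k):
    """Exponential map at the origin: tangent vector → ball point."""
    sc = 1.0 / _sqrt_k(curvature_k)  # √c
    n = ad.norm(v)
    scaled = ad.clamp(sc * n, min_value=1e-12)
    return project(ad.tanh(scaled) / scaled * v, curvature_k)


def logmap0(x, curvature_k):
    """Logarithmic map at the origin: ball point → tangent vector."""
    sc = 1.0 / _sqrt_k(curvature_k)
    n = ad.norm(x)
    scaled = ad.clamp(sc * n, min_value=1e-12, max_value=1.0 - ATANH_EPS)
    return ad.atanh(scaled) / scaled * x


def mobius_add(x, y, curvature_k):
    """Möbius addition x ⊕ y on the ball of curvature −1/K."""
    c = 1.0 / curvature_k
    x2 = ad.sum(x * x, axis=-1, keepdims=True)
    y2 = ad.sum(y * y, axis=-1, keepdims=True)
    xy = ad.sum(x * y, axis=-1, keepdims=True)
    num = (1.0 + 2.0 * c * xy + c * y2) * x + (1.0 - c * x2) * y
    den = 1.0 + 2.0 * c * xy + (c**2) * x2 * y2
    return project(num / ad.clamp(den, min_value=1e-12), curvature_k)


def mobius_matvec(weight, x, curvature_k):
    """Möbius matrix-vector product W ⊗ x = exp₀(log₀(x)·Wᵀ)."""
    return expmap0(ad.matmul(logmap0(x, curvature_k), _transpose(weight)), curvature_k)


def _transpose(w):
    return w.T if isinstance(w, ad.Tensor) else ad.data_of(w).T


def distance(x, y, curvature_k):
    """Geodesic distance d^K(x, y) = (2/√c)·artanh(√c‖(−x) ⊕ y‖)."""
    sc = 1.0 / _sqrt_k(curvature_k)
    diff = mobius_add(-1.0 * x, y, curvature_k)
    n = ad.norm(diff, keepdims=False)
    return (2.0 / sc) * ad.atanh(ad.clamp(sc * n, max_value=1.0 - ATANH_EPS))


def squared_distance(x, y, curvature_k):
    d = distance(x, y, curvature_k)
    return d * d
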