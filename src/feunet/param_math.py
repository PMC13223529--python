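"""Closed-form trainable-parameter budgets and an empirical counter.

Two independent routes to the same number:

* :func:`closed_form_params` evaluates the architecture's counting algebra
  directly from the configuration, without building anything;
* :func:`empirical_params` enumerates the parameter arrays of a constructed
  model.

They must agree exactly; the published budget table for the vgg16-style
backbone (N in 3..6, n in {8, 16, 32, 64}) and the 1.93 M resnet34-backbone
figure are reproduced at the printed rounding.

Counting convention (matches the constructed network): convolution weights
only — convolutions carry no bias, batch normalization carries no learnable
affine pair — except the final 1x1 classifier, which keeps its bias.  The
per-decoder-level count at level i with mirrored width d_i = 2^(i-1)*n is

    P_i = k^2 * d_i * S_i      (Gamma adapter convs over all sources)
        + k^2 * B_i * d_i^2    (Theta fusion conv on the concatenation)
        + k^2 * d_i^2          (second Theta conv)

where S_i is the summed channel count of the sources (all N encoder levels,
plus the deeper decoder's 2^i*n when i < N-1) and B_i the branch count
(N+1 below the bottleneck, N at i = N-1, where the deeper input is the
bottleneck itself and enters once).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .config import ConfigurationError, NetworkConfig

__all__ = [
    "ParamReport",
    "closed_form_params",
    "empirical_params",
    "param_ratio",
    "param_grid",
]

#: Published reference parameter budgets, in millions (comparison networks).
REFERENCE_PARAMS_M = {
    "unet_vgg16": 39.39,
    "unet_resnet101": 55.90,
    "unetpp_vgg16": 47.18,
    "unetpp_resnet101": 63.76,
    "unet3p_vgg16": 26.97,
    "unet3p_resnet101": 43.55,
    "smallest_brats_competitor": 3.27,
}


@dataclass
class ParamReport:
    per_layer: list  # (layer name, parameter count)
    total: int
    total_M: float
    formula_total: int

    def consistent(self) -> bool:
        return self.total == sum(c for _, c in self.per_layer) and self.total == self.formula_total


def _decoder_params(N: int, n: int, k: int) -> int:
    total = 0
    enc_sum = (2**N - 1) * n  # summed widths of all N encoder levels
    for i in range(1, N):
        d = n * 2 ** (i - 1)
        if i < N - 1:
            src_sum = enc_sum + n * 2**i  # + deeper decoder output
            branches = N + 1
        else:
            src_sum = enc_sum  # deeper input IS the bottleneck; fed once
            branches = N
        total += k * k * d * src_sum          # Gamma adapters
        total += k * k * branches * d * d     # Theta conv on the concatenation
        total += k * k * d * d                # second Theta conv
    return total


def _vgg_encoder_params(N: int, n: int, n0: int, k: int) -> int:
    total = k * k * n0 * n + k * k * n * n  # stage 1: double conv at width n
    for i in range(2, N + 1):
        c_in, c = n * 2 ** (i - 2), n * 2 ** (i - 1)
        total += k * k * c_in * c + k * k * c * c
    return total


def _resnet_encoder_params(N: int, n: int, n0: int, k: int, w) -> int:
    total = k * k * n0 * n  # 3x3 stride-1 stem at width n (level 1)
    for i in range(2, N + 1):
        c_in, c = n * 2 ** (i - 2), n * 2 ** (i - 1)
        blocks = w[i - 2]
        total += k * k * c_in * c + k * k * c * c + c_in * c  # stride-2 block + 1x1 projection
        total += (blocks - 1) * 2 * k * k * c * c
    return total


def closed_form_params(config: NetworkConfig) -> int:
    """Total trainable parameters from the counting algebra alone."""
    config.validate()
    N, n, n0, nc, k = config.N, config.n, config.n0, config.nc, config.k_e
    if config.backbone == "vgg16":
        enc = _vgg_encoder_params(N, n, n0, k)
    else:
        enc = _resnet_encoder_params(N, n, n0, k, config.w)
    return enc + _decoder_params(N, n, k) + n * nc + nc  # + 1x1 classifier with bias


def empirical_params(model) -> ParamReport:
    """Exact enumeration of a built model's trainable arrays, per layer."""
    per_layer = [(p.name, p.size) for p in model.parameters()]
    total = sum(c for _, c in per_layer)
    formula = closed_form_params(model.config)
    return ParamReport(per_layer, total, round(total / 1e6, 3), formula)


def param_ratio(count_M: float, reference_M: float) -> float:
    """Percentage of a reference budget, rounded to 2 decimals."""
    if reference_M <= 0:
        raise ValueError(f"reference parameter count must be positive, got {reference_M}")
    return round(100.0 * count_M / reference_M, 2)


def param_grid(
    N_values=(3, 4, 5, 6),
    n_values=(8, 16, 32, 64),
    n0: int = 3,
    nc: int = 2,
) -> list[dict]:
    """The budget table for the vgg16-style backbone over an (N, n) grid."""
    rows = []
    for N in N_values:
        for n in n_values:
            cfg = NetworkConfig(backbone="vgg16", N=N, n=n, n0=n0, nc=nc)
            total = closed_form_params(cfg)
            rows.append({"N": N, "n": n, "params": total, "params_M": round(total / 1e6, 3)})
    return rows


def grid_as_tsv(rows: list[dict]) -> str:
    out = ["N\tn\tparams\tparams_M"]
    out += [f"{r['N']}\t{r['n']}\t{r['params']}\t{r['params_M']:.3f}" for r in rows]
    return "\n".join(out)


def grid_as_json(rows: list[dict]) -> str:
    return json.dumps(rows, indent=2)
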