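"""Analytic complexity accounting for layer graphs: parameters, mult-adds, disk.

Counts are derived purely from the structural layer descriptors (kernel sizes,
channel counts, strides, feature-map lengths) -- never by introspecting the
instantiated weight arrays -- so the module doubles as an independent oracle
for the graphs actually built by :mod:`ecgage.models`.

Conventions (documented because published complexity tables rarely state them):

* one *mult-add* = one fused multiply-accumulate, batch size 1, forward pass
  only; convolution bias additions, normalization, activations and pooling are
  excluded;
* temporal layers whose weights are shared across the 12 leads cost 12x their
  single-lead mult-adds but contribute their parameters once;
* serialized size is decimal megabytes at 4 bytes (float32) per parameter;
* batch-norm scale/shift are trainable parameters (2 per channel); running
  statistics are reported separately as buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import LayerGraph

_PARAM_FREE = {"relu", "maxpool", "dropout", "flatten", "reshape", "add"}


def _layer_params(d: dict) -> tuple[int, int]:
    """(trainable, buffer) parameter count of one descriptor."""
    kind = d["kind"]
    if kind in ("conv1d", "spatial_conv"):
        return d["in_ch"] * d["out_ch"] * d["kernel"] + d["out_ch"], 0
    if kind == "linear":
        return d["d_in"] * d["d_out"] + d["d_out"], 0
    if kind == "batchnorm":
        return 2 * d["ch"], 2 * d["ch"]
    if kind in _PARAM_FREE:
        return 0, 0
    raise ValueError(f"unknown layer kind {kind!r} in descriptor {d['name']}")


def _layer_macs(d: dict) -> int:
    kind = d["kind"]
    if kind in ("conv1d", "spatial_conv"):
        return (d["out_len"] * d["out_ch"] * d["in_ch"] * d["kernel"]
                * d.get("lead_mult", 1))
    if kind == "linear":
        return d["d_in"] * d["d_out"]
    if kind in _PARAM_FREE or kind == "batchnorm":
        return 0
    raise ValueError(f"unknown layer kind {kind!r} in descriptor {d['name']}")


@dataclass
class ComplexityReport:
    arch: str
    input_len: int
    trainable_params: int = 0
    total_params: int = 0
    buffer_params: int = 0
    macs: int = 0
    per_layer: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def macs_g(self) -> float:
        return round(self.macs / 1e9, 2)

    @property
    def disk_mb(self) -> float:
        return round(4 * self.total_params / 1e6, 2)

    def to_frame(self) -> pd.DataFrame:
        """One-row summary mirroring the published table columns."""
        return pd.DataFrame([{
            "Architecture": self.arch,
            "Input Length": self.input_len,
            "Parameter Count": self.total_params,
            "Disk Utilization (MB)": self.disk_mb,
            "Multiplications-additions (G)": self.macs_g,
        }])


def count_params(graph: LayerGraph) -> ComplexityReport:
    """Analytic parameter count from the graph's layer descriptors."""
    rows, trainable, buffers = [], 0, 0
    for d in graph.descriptors():
        p, b = _layer_params(d)
        trainable += p
        buffers += b
        rows.append({"layer": d["name"], "kind": d["kind"], "params": p,
                     "buffers": b, "out_len": d["out_len"]})
    rep = ComplexityReport(graph.arch, graph.input_len,
                           trainable_params=trainable, total_params=trainable,
                           buffer_params=buffers, per_layer=pd.DataFrame(rows))
    return rep


def count_macs(graph: LayerGraph, input_len: int | None = None) -> ComplexityReport:
    """Forward-pass fused multiply-accumulate count at batch size 1."""
    if input_len is not None and input_len != graph.input_len:
        raise ValueError(f"graph was built for input_len {graph.input_len}, "
                         f"not {input_len}; rebuild for the target length")
    rep = count_params(graph)
    macs = []
    for d in graph.descriptors():
        macs.append(_layer_macs(d))
    rep.per_layer = rep.per_layer.assign(macs=macs)
    rep.macs = int(sum(macs))
    return rep


def disk_mb(graph: LayerGraph) -> float:
    """Serialized weight size in decimal MB at 4 bytes per parameter."""
    return count_params(graph).disk_mb


def report(graph: LayerGraph) -> ComplexityReport:
    return count_macs(graph)


def crosscheck_params(graph: LayerGraph) -> pd.DataFrame:
    """Per-layer comparison of analytic counts vs the instantiated arrays.

    The analytic route walks descriptors; the introspective route sums the
    sizes of the parameter tensors actually allocated by the layer stack.
    The two must agree layer by layer.
    """
    analytic = {}
    for d in graph.descriptors():
        p, _ = _layer_params(d)
        if p:
            analytic[d["name"]] = p
    actual: dict[str, int] = {}
    for p in graph.parameters():
        layer = p.name.rsplit(".", 1)[0]
        actual[layer] = actual.get(layer, 0) + p.value.size
    names = sorted(set(analytic) | set(actual))
    return pd.DataFrame({
        "layer": names,
        "analytic": [analytic.get(n, 0) for n in names],
        "instantiated": [actual.get(n, 0) for n in names],
    })
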