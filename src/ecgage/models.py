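"""The two 1-D CNN architectures for ECG age regression, as explicit layer graphs.

Both networks map a 12-lead signal batch ``(N, 12, L)`` to one scalar age per
record.  ``L`` must sit on the 1,024-sample grid (see :mod:`ecgage.preprocess`).

* **AttiaNet** -- eight temporal convolutional blocks whose weights are shared
  across the 12 leads (each block: convolution -> batch norm -> ReLU -> max
  pool), one spatial block fusing all leads, then an MLP regression head.
* **ResNet1D** -- an initial convolutional block followed by four residual
  blocks; each block's main path is conv17 -> BN -> ReLU -> dropout -> conv17
  (the second conv strided by 4), its skip path maxpool(4) -> 1x1 conv, merged
  before the closing BN -> ReLU -> dropout.  Channels grow 64->128->192->256->320
  while the temporal axis shrinks 4x per block.

The committed configurations (`ATTIA_DEFAULT`, `RESNET_DEFAULT`) are the result
of a scripted calibration against the published per-rate parameter totals
(AttiaNet 593,505..599,649; ResNet1D 6,940,065..7,021,985), the 6,144 / 81,920
parameters-per-4,096-samples growth slopes, AttiaNet's 1.57 G forward
mult-adds at the 5,120-sample input, and the 3.22 M trainable parameters under
the fine-tuning freeze.  See docs/methods.md for the calibration argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

GRID = 1024
N_LEADS = 12


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttiaConfig:
    """Free dimensions of the AttiaNet family.

    ``filters``/``kernels``/``pools`` describe the temporal blocks (kernel
    schedule: 7 for the initial block, 5 for intermediate, 3 for deep blocks);
    a pool window of 1 means no pooling in that block.  ``spatial_filters``
    convolve across the stacked lead axis with a kernel spanning all 12 leads.
    ``head`` lists the hidden widths of the MLP regression head.
    """

    filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64, 64, 64)
    kernels: tuple[int, ...] = (7, 5, 5, 5, 5, 5, 3, 3)
    pools: tuple[int, ...] = (1, 1, 1, 1, 4, 4, 2, 2)
    spatial_filters: int = 12
    spatial_pool: int = 2
    head: tuple[int, ...] = (16, 893, 561)

    def __post_init__(self):
        if not (len(self.filters) == len(self.kernels) == len(self.pools)):
            raise ValueError("filters/kernels/pools must have equal length")
        if any(k % 2 == 0 for k in self.kernels):
            raise ValueError("temporal kernels must be odd")

    @property
    def reduction(self) -> int:
        r = self.spatial_pool
        for p in self.pools:
            r *= p
        return r


@dataclass(frozen=True)
class ResNetConfig:
    """Free dimensions of the ResNet1D family."""

    initial_filters: int = 64
    initial_kernel: int = 17
    block_channels: tuple[int, ...] = (128, 192, 256, 320)
    block_kernel: int = 17
    block_reduction: int = 4
    dropout: float = 0.5
    head: tuple[int, ...] = (16, 600, 300)

    @property
    def reduction(self) -> int:
        return self.block_reduction ** len(self.block_channels)


ATTIA_DEFAULT = AttiaConfig()
RESNET_DEFAULT = ResNetConfig()

#: a deliberately small AttiaNet for desk-scale training studies
ATTIA_REDUCED = AttiaConfig(filters=(8, 16, 16, 16), kernels=(7, 5, 5, 3),
                            pools=(4, 4, 4, 2), spatial_filters=12,
                            spatial_pool=2, head=(16, 32, 16))

#: a deliberately small ResNet1D for desk-scale transfer studies
RESNET_REDUCED = ResNetConfig(initial_filters=8, initial_kernel=9,
                              block_channels=(12, 16, 20, 24),
                              block_kernel=9, dropout=0.1, head=(8, 12, 6))


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------

class ResidualBlock(nn.Layer):
    """One ResNet1D residual unit (main conv pair + pooled 1x1 skip)."""

    def __init__(self, in_ch, out_ch, kernel, reduction, dropout, rng, name):
        self.name = name
        self.in_ch, self.out_ch = in_ch, out_ch
        self.reduction = reduction
        self.conv1 = nn.Conv1d(in_ch, out_ch, kernel, 1, rng, f"{name}.conv1")
        self.bn1 = nn.BatchNorm1d(out_ch, name=f"{name}.bn1")
        self.relu1 = nn.ReLU(f"{name}.relu1")
        self.drop1 = nn.Dropout(dropout, rng, f"{name}.drop1")
        self.conv2 = nn.Conv1d(out_ch, out_ch, kernel, reduction, rng, f"{name}.conv2")
        self.skip_pool = nn.MaxPool1d(reduction, f"{name}.skip_pool")
        self.skip_conv = nn.Conv1d(in_ch, out_ch, 1, 1, rng, f"{name}.skip_conv")
        self.bn2 = nn.BatchNorm1d(out_ch, name=f"{name}.bn2")
        self.relu2 = nn.ReLU(f"{name}.relu2")
        self.drop2 = nn.Dropout(dropout, rng, f"{name}.drop2")

    # descriptor order documents the operator sequence for the graph audit
    _main = ("conv1", "bn1", "relu1", "drop1", "conv2")
    _skip = ("skip_pool", "skip_conv")
    _tail = ("bn2", "relu2", "drop2")

    def sublayers(self):
        for attr in self._main + self._skip + self._tail:
            yield getattr(self, attr)

    def out_len(self, in_len):
        return in_len // self.reduction

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.drop1.forward(h, train)
        h = self.conv2.forward(h, train)
        s = self.skip_pool.forward(x, train)
        s = self.skip_conv.forward(s, train)
        y = self.bn2.forward(h + s, train)
        y = self.relu2.forward(y, train)
        return self.drop2.forward(y, train)

    def backward(self, dy):
        d = self.drop2.backward(dy)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        dh = self.conv2.backward(d)
        dh = self.drop1.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        ds = self.skip_conv.backward(d)
        dx = dx + self.skip_pool.backward(ds)
        return dx

    def params(self):
        out = []
        for lay in self.sublayers():
            out.extend(lay.params())
        return out

    def buffers(self):
        out = {}
        for lay in self.sublayers():
            out.update(lay.buffers())
        return out

    def descriptors(self, in_len):
        descs = []
        for attr in self._main:
            lay = getattr(self, attr)
            descs.append(lay.descriptor(in_len))
            in_len = lay.out_len(in_len)
        skip_len = descs[0]["in_len"]
        for attr in self._skip:
            lay = getattr(self, attr)
            d = lay.descriptor(skip_len)
            d["path"] = "skip"
            descs.append(d)
            skip_len = lay.out_len(skip_len)
        descs.append(dict(name=f"{self.name}.add", kind="add",
                          in_len=in_len, out_len=in_len))
        for attr in self._tail:
            lay = getattr(self, attr)
            descs.append(lay.descriptor(in_len))
        return descs


class LayerGraph:
    """An ordered layer graph with forward/backward and structural metadata."""

    def __init__(self, arch: str, input_len: int, config):
        self.arch = arch
        self.input_len = int(input_len)
        self.config = config
        self.stages: list[nn.Layer] = []       # executed in order
        self._lead_shared: set[str] = set()    # stage names run per lead

    # -- execution ---------------------------------------------------------
    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != N_LEADS or x.shape[2] != self.input_len:
            raise ValueError(
                f"{self.arch}: expected batch shaped (N, {N_LEADS}, {self.input_len}), "
                f"got {x.shape}")
        self._n = x.shape[0]
        if self._lead_shared:
            # leads become independent channel-1 records: (N*12, L, 1)
            x = x.reshape(-1, self.input_len)[:, :, None]
        else:
            x = np.ascontiguousarray(x.transpose(0, 2, 1))  # (N, L, 12)
        for stage in self.stages:
            x = stage.forward(x, train)
        return x[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        d = np.asarray(dpred, dtype=np.float32)[:, None]
        for stage in reversed(self.stages):
            d = stage.backward(d)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[nn.Param]:
        out = []
        for s in self.stages:
            out.extend(s.params())
        return out

    def named_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for s in self.stages:
            out.update(s.buffers())
        return out

    def num_params(self, trainable_only: bool = False) -> int:
        return sum(p.value.size for p in self.parameters()
                   if p.trainable or not trainable_only)

    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {p.name: p.value.copy() for p in self.parameters()}
        for k, v in self.named_buffers().items():
            sd[k] = v.copy()
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        mismatches = []
        for p in self.parameters():
            if p.name not in sd:
                mismatches.append(f"missing {p.name}")
            elif sd[p.name].shape != p.value.shape:
                mismatches.append(
                    f"{p.name}: expected {p.value.shape}, got {sd[p.name].shape}")
        if mismatches:
            raise ValueError("weight manifest mismatch: " + "; ".join(mismatches))
        for p in self.parameters():
            p.value[...] = sd[p.name]
        for s in self.stages:
            for k in s.buffers():
                if k in sd:
                    s.buffers()[k][...] = sd[k]

    # -- structure ---------------------------------------------------------
    def descriptors(self) -> list[dict]:
        descs = []
        L = self.input_len
        for s in self.stages:
            if isinstance(s, ResidualBlock):
                descs.extend(s.descriptors(L))
                L = s.out_len(L)
            elif isinstance(s, _MergeLeads):
                descs.append(s.descriptor(L))
            else:
                descs.append(s.descriptor(L))
                L = s.out_len(L)
        return descs

    def residual_blocks(self) -> list[ResidualBlock]:
        return [s for s in self.stages if isinstance(s, ResidualBlock)]


class _MergeLeads(nn.Layer):
    """Reshape (N*12, L, C) -> (N, L, 12*C): stack per-lead features on channels."""

    name = "_merge_leads"

    def __init__(self, ch: int):
        self.ch = ch

    def forward(self, x, train=False):
        n = x.shape[0] // N_LEADS
        self._shape = x.shape
        return np.ascontiguousarray(
            x.reshape(n, N_LEADS, x.shape[1], self.ch).transpose(0, 2, 1, 3)
        ).reshape(n, x.shape[1], N_LEADS * self.ch)

    def backward(self, dy):
        n, L, _ = dy.shape
        return np.ascontiguousarray(
            dy.reshape(n, L, N_LEADS, self.ch).transpose(0, 2, 1, 3)
        ).reshape(self._shape)

    def descriptor(self, in_len):
        return dict(name=self.name, kind="reshape", in_len=in_len, out_len=in_len)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_input_len(input_len: int, reduction: int, arch: str) -> None:
    if input_len % GRID != 0 or input_len <= 0:
        raise ValueError(f"{arch}: input_len {input_len} is not on the "
                         f"{GRID}-sample grid")
    if input_len < reduction:
        raise ValueError(f"{arch}: input_len {input_len} is shorter than the "
                         f"net temporal reduction {reduction} of the stacked pools")
    if input_len % reduction != 0:
        raise ValueError(f"{arch}: input_len {input_len} not divisible by the "
                         f"net temporal reduction {reduction}")


def build_attianet(config: AttiaConfig = ATTIA_DEFAULT,
                   input_len: int = 5120, seed: int = 0) -> LayerGraph:
    """Construct an AttiaNet graph for 12-lead input of ``input_len`` samples."""
    _check_input_len(input_len, config.reduction, "AttiaNet")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = LayerGraph("AttiaNet", input_len, config)
    in_ch = 1
    for i, (f, k, p) in enumerate(zip(config.filters, config.kernels, config.pools), 1):
        # Conv_Block_m: maxpool(relu(BN(conv(x))))  -- weights shared across leads
        g.stages.append(nn.Conv1d(in_ch, f, k, 1, rng, f"temporal{i}.conv",
                                  lead_mult=N_LEADS))
        g.stages.append(nn.BatchNorm1d(f, name=f"temporal{i}.bn"))
        g.stages.append(nn.ReLU(f"temporal{i}.relu"))
        g.stages.append(nn.MaxPool1d(p, f"temporal{i}.pool"))
        g._lead_shared.add(f"temporal{i}")
        in_ch = f
    g.stages.append(_MergeLeads(in_ch))
    # spatial block: one kernel position spans all 12 leads' feature stacks
    g.stages.append(nn.Conv1d(N_LEADS * in_ch, config.spatial_filters, 1, 1, rng,
                              "spatial.conv", kind="spatial_conv"))
    g.stages.append(nn.BatchNorm1d(config.spatial_filters, name="spatial.bn"))
    g.stages.append(nn.ReLU("spatial.relu"))
    g.stages.append(nn.MaxPool1d(config.spatial_pool, "spatial.pool"))
    g.stages.append(nn.Flatten("flatten"))
    feat = (input_len // config.reduction) * config.spatial_filters
    widths = list(config.head)
    for j, w in enumerate(widths, 1):
        g.stages.append(nn.Linear(feat, w, rng, f"head.fc{j}"))
        g.stages.append(nn.ReLU(f"head.relu{j}"))
        feat = w
    g.stages.append(nn.Linear(feat, 1, rng, "head.out"))
    return g


def build_resnet1d(config: ResNetConfig = RESNET_DEFAULT,
                   input_len: int = 5120, seed: int = 0) -> LayerGraph:
    """Construct a ResNet1D graph for 12-lead input of ``input_len`` samples."""
    _check_input_len(input_len, config.reduction, "ResNet1D")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = LayerGraph("ResNet1D", input_len, config)
    g.stages.append(nn.Conv1d(N_LEADS, config.initial_filters,
                              config.initial_kernel, 1, rng, "initial.conv"))
    g.stages.append(nn.BatchNorm1d(config.initial_filters, name="initial.bn"))
    g.stages.append(nn.ReLU("initial.relu"))
    in_ch = config.initial_filters
    for i, out_ch in enumerate(config.block_channels, 1):
        g.stages.append(ResidualBlock(in_ch, out_ch, config.block_kernel,
                                      config.block_reduction, config.dropout,
                                      rng, f"resblock{i}"))
        in_ch = out_ch
    g.stages.append(nn.Flatten("flatten"))
    feat = (input_len // config.reduction) * in_ch
    for j, w in enumerate(config.head, 1):
        g.stages.append(nn.Linear(feat, w, rng, f"head.fc{j}"))
        g.stages.append(nn.ReLU(f"head.relu{j}"))
        feat = w
    g.stages.append(nn.Linear(feat, 1, rng, "head.out"))
    return g


def forward(graph: LayerGraph, batch: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass: one predicted age per record."""
    return graph.forward(batch, train=False)


# ---------------------------------------------------------------------------
# fine-tuning freeze
# ---------------------------------------------------------------------------

def freeze_scope(graph: LayerGraph, boundary: str = "through_resblock3"
                 ) -> dict[str, bool]:
    """Mark parameters trainable/frozen for fine-tuning.

    ``through_resblock3`` freezes the initial block, residual blocks 1-3 and
    the MLP head's hidden layers; the fourth residual block and the scalar
    output layer remain trainable.  Frozen batch-norm layers are held in
    inference mode (running statistics, no updates).  Returns the
    name -> trainable mask.
    """
    if boundary == "none":
        for p in graph.parameters():
            p.trainable = True
        for s in _all_layers(graph):
            if isinstance(s, nn.BatchNorm1d):
                s.frozen = False
        return {p.name: True for p in graph.parameters()}
    if boundary != "through_resblock3":
        raise ValueError(f"unknown freeze boundary {boundary!r}")
    blocks = graph.residual_blocks()
    if len(blocks) < 4:
        raise ValueError("freeze boundary 'through_resblock3' requires a "
                         "ResNet1D graph with four residual blocks")
    trainable_prefixes = (blocks[3].name + ".", "head.out.")
    mask = {}
    for s in _all_layers(graph):
        for p in s.params():
            p.trainable = p.name.startswith(trainable_prefixes)
            mask[p.name] = p.trainable
        if isinstance(s, nn.BatchNorm1d):
            s.frozen = not s.name.startswith(trainable_prefixes)
    return mask


def _all_layers(graph: LayerGraph):
    for s in graph.stages:
        if isinstance(s, ResidualBlock):
            yield from s.sublayers()
        else:
            yield s


# ---------------------------------------------------------------------------
# serialization: raw float32 blob + JSON manifest (4 bytes per parameter)
# ---------------------------------------------------------------------------

def save_weights(graph: LayerGraph, path) -> None:
    import json
    import pathlib
    path = pathlib.Path(path)
    manifest, blobs, offset = {}, [], 0
    for p in graph.parameters():
        arr = p.value.astype(np.float32)
        manifest[p.name] = {"shape": list(arr.shape), "offset": offset}
        blobs.append(arr.tobytes())
        offset += arr.size
    for name, buf in graph.named_buffers().items():
        arr = buf.astype(np.float32)
        manifest[name] = {"shape": list(arr.shape), "offset": offset, "buffer": True}
        blobs.append(arr.tobytes())
        offset += arr.size
    path.with_suffix(".bin").write_bytes(b"".join(blobs))
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_weights(graph: LayerGraph, path) -> None:
    import json
    import pathlib
    path = pathlib.Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    raw = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype=np.float32)
    sd = {}
    for name, meta in manifest.items():
        size = int(np.prod(meta["shape"])) if meta["shape"] else 1
        sd[name] = raw[meta["offset"]:meta["offset"] + size].reshape(meta["shape"])
    graph.load_state_dict(sd)
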