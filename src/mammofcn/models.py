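"""Backbone construction and patch-to-whole-image conversion.

A patch classifier f maps a fixed-size patch to c=5 class probabilities
(background, benign/malignant calcification, benign/malignant mass). Because
f is all-convolutional with a global-average-pooling head, its trunk can be
applied to a whole image M, yielding a u x v x c grid of patch scores (the
"heatmap"). Appending top layers g gives an end-to-end trainable whole-image
classifier h = g(f(M)) with d=2 outputs (malignant vs nonmalignant).

Backbones are described by a small block grammar: a VGG block "NxK" is K
3x3 convolutions of depth N followed by 2x2 max pooling; a residual block
"[L-M-N]xK" is K bottleneck units (1x1, 3x3, 1x1 convolutions with identity
shortcuts), the first unit carrying the block's stride.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import nn

PATCH_CLASSES = ["background", "benign_calc", "malignant_calc",
                 "benign_mass", "malignant_mass"]
N_PATCH_CLASSES = len(PATCH_CLASSES)


class SpecError(ValueError):
    pass


@dataclass
class BlockSpec:
    kind: str                      # 'vgg' | 'resnet_bottleneck'
    pattern: tuple                 # vgg: (N, K); resnet: ((L, M, N), K)
    batch_norm: bool = False
    stride: int = 2                # downsampling factor at block entry/exit

    def __post_init__(self):
        if self.kind not in ("vgg", "resnet_bottleneck"):
            raise SpecError(f"unknown block kind {self.kind!r}")
        if self.kind == "vgg":
            n, k = self.pattern
            if n < 1 or k < 1:
                raise SpecError(f"invalid vgg pattern {self.pattern}")
        else:
            depths, k = self.pattern
            if k < 1 or any(d < 1 for d in depths):
                raise SpecError(f"invalid resnet pattern {self.pattern}")

    @classmethod
    def parse(cls, text: str, batch_norm: bool | None = None) -> "BlockSpec":
        """Parse grammar strings like '256x1' or '[512-512-1024]x2'."""
        text = text.strip()
        m = re.fullmatch(r"\[(\d+)-(\d+)-(\d+)\]x(\d+)", text)
        if m:
            l, mm, n, k = map(int, m.groups())
            return cls("resnet_bottleneck", ((l, mm, n), k),
                       batch_norm=True if batch_norm is None else batch_norm)
        m = re.fullmatch(r"(\d+)x(\d+)", text)
        if m:
            n, k = map(int, m.groups())
            return cls("vgg", (n, k),
                       batch_norm=False if batch_norm is None else batch_norm)
        raise SpecError(f"cannot parse block grammar {text!r}")

    def grammar(self) -> str:
        if self.kind == "vgg":
            return f"{self.pattern[0]}x{self.pattern[1]}"
        (l, m, n), k = self.pattern
        return f"[{l}-{m}-{n}]x{k}"


@dataclass
class BackboneSpec:
    blocks: list[BlockSpec]
    input_size: int = 224
    n_patch_classes: int = N_PATCH_CLASSES
    in_channels: int = 1
    padding: str = "same"
    stem: str | None = None       # 'resnet' for 7x7/2 conv + 3x3/2 maxpool
    name: str = "custom"

    def __post_init__(self):
        if self.n_patch_classes < 2:
            raise SpecError("need at least 2 patch classes")
        if not self.blocks:
            raise SpecError("backbone needs at least one block")


@dataclass
class TopSpec:
    variant: str = "conv_blocks_no_heatmap"
    top_blocks: list[BlockSpec] = field(default_factory=list)
    heatmap_activation: str = "relu"     # 'relu' | 'softmax'
    fc_sizes: tuple[int, int] = (64, 32)
    pool_size: int = 5
    n_image_classes: int = 2
    init_heatmap_from_head: bool = True

    VARIANTS = ("conv_blocks_no_heatmap", "heatmap_then_conv_blocks",
                "heatmap_maxpool_fc_shortcut")

    def __post_init__(self):
        if self.variant not in self.VARIANTS:
            raise SpecError(f"unknown top variant {self.variant!r}")
        if len(self.top_blocks) > 2:
            raise SpecError("at most two top blocks")
        if self.heatmap_activation not in ("relu", "softmax"):
            raise SpecError(f"unknown heatmap activation {self.heatmap_activation!r}")
        if self.variant == "heatmap_maxpool_fc_shortcut" and self.pool_size is None:
            raise SpecError("FC-top variant requires a pool size")


@dataclass
class NetworkHandle:
    """A realized network plus the metadata staged training needs."""

    net: nn.Sequential
    kind: str                          # 'patch' | 'whole_image'
    n_classes: int
    input_size: int | None = None
    provenance: str = "random init"
    source_layer_count: int = 0        # layers inherited from the patch net
    trunk_channels: int = 0
    spec: object = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a (N,1,H,W) batch (inference mode)."""
        return self.net.forward(np.asarray(x, dtype=np.float32), train=False)


@dataclass
class Heatmap:
    """Grid of patch-classifier responses over a whole image."""

    grid: np.ndarray                   # u x v x c
    activation_kind: str
    stride: int
    receptive_field: int
    grid_same_padding: tuple[int, int] | None = None   # ceil(dim/stride)
    grid_valid_padding: tuple[int, int] | None = None  # floor((dim-rf)/stride)+1


# ---------------------------------------------------------------------------
# Builders

def _vgg_block_layers(spec: BlockSpec, in_ch: int, rng, tag: str):
    n, k = spec.pattern
    layers: list[nn.Layer] = []
    ch = in_ch
    for i in range(k):
        layers.append(nn.Conv2d(ch, n, 3, 1, "same", bias=True, rng=rng,
                                name=f"{tag}.conv{i}"))
        if spec.batch_norm:
            layers.append(nn.BatchNorm2d(n, name=f"{tag}.bn{i}"))
        layers.append(nn.ReLU())
        ch = n
    layers.append(nn.MaxPool2d(2, 2, name=f"{tag}.pool"))
    return layers, ch


def _resnet_block_layers(spec: BlockSpec, in_ch: int, rng, tag: str):
    depths, k = spec.pattern
    layers: list[nn.Layer] = []
    ch = in_ch
    for i in range(k):
        stride = spec.stride if i == 0 else 1
        layers.append(nn.BottleneckUnit(ch, depths, stride=stride, rng=rng,
                                        name=f"{tag}.u{i}"))
        ch = depths[2]
    return layers, ch


def _block_layers(spec: BlockSpec, in_ch: int, rng, tag: str):
    if spec.kind == "vgg":
        return _vgg_block_layers(spec, in_ch, rng, tag)
    return _resnet_block_layers(spec, in_ch, rng, tag)


def build_patch_classifier(spec: BackboneSpec, init: str | dict = "random",
                           seed: int = 0) -> NetworkHandle:
    """Realize a backbone spec as a patch classifier trunk + GAP + FC head."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    ch = spec.in_channels
    if spec.stem == "resnet":
        layers.append(nn.Conv2d(ch, 64, 7, 2, spec.padding, bias=False, rng=rng,
                                name="stem.conv"))
        layers.append(nn.BatchNorm2d(64, name="stem.bn"))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2d(3, 2, padding=spec.padding, name="stem.pool"))
        ch = 64
    for bi, block in enumerate(spec.blocks):
        try:
            blayers, ch = _block_layers(block, ch, rng, f"b{bi}")
        except SpecError:
            raise
        except Exception as exc:  # pragma: no cover
            raise SpecError(f"cannot build block {bi} ({block.grammar()}): {exc}")
        layers.extend(blayers)
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(ch, spec.n_patch_classes, rng=rng, name="head.fc"))
    layers.append(nn.Softmax())
    net = nn.Sequential(layers)
    provenance = "random init"
    if isinstance(init, dict):
        load_weights(net, init)
        provenance = "externally pre-trained"
    elif init != "random":
        raise SpecError(f"unknown init {init!r}")
    return NetworkHandle(net=net, kind="patch", n_classes=spec.n_patch_classes,
                         input_size=spec.input_size, provenance=provenance,
                         trunk_channels=ch, spec=spec)


def vgg16_backbone(in_channels: int = 1) -> BackboneSpec:
    """The 16-layer VGG design with its two FC layers replaced by global
    average pooling: five blocks 64x2, 128x2, 256x3, 512x3, 512x3."""
    blocks = [BlockSpec.parse(g) for g in
              ("64x2", "128x2", "256x3", "512x3", "512x3")]
    return BackboneSpec(blocks=blocks, input_size=224, in_channels=in_channels,
                        name="VGG16")


def resnet50_backbone(in_channels: int = 1) -> BackboneSpec:
    """The 50-layer residual network: 7x7/2 stem + max pool, then bottleneck
    stages [64-64-256]x3, [128-128-512]x4, [256-256-1024]x6, [512-512-2048]x3."""
    stage_strides = (1, 2, 2, 2)
    grammars = ("[64-64-256]x3", "[128-128-512]x4",
                "[256-256-1024]x6", "[512-512-2048]x3")
    blocks = []
    for g, s in zip(grammars, stage_strides):
        b = BlockSpec.parse(g)
        b.stride = s
        blocks.append(b)
    return BackboneSpec(blocks=blocks, input_size=224, in_channels=in_channels,
                        stem="resnet", name="Resnet50")


def tiny_backbone(patch_size: int = 32, widths=(8, 16, 32),
                  n_patch_classes: int = N_PATCH_CLASSES,
                  padding: str = "same") -> BackboneSpec:
    """A small VGG-grammar backbone for CPU-scale experiments."""
    blocks = [BlockSpec(kind="vgg", pattern=(w, 1), batch_norm=True)
              for w in widths]
    return BackboneSpec(blocks=blocks, input_size=patch_size,
                        n_patch_classes=n_patch_classes, padding=padding,
                        name="tiny")


# ---------------------------------------------------------------------------
# Geometry and parameter oracles

def receptive_field(obj) -> tuple[int, int]:
    """(receptive-field side, cumulative stride) of a conv/pool chain.

    Layer walk: starting from rf=1, jump=1, each layer with kernel k and
    stride s applies rf += (k-1)*jump then jump *= s. Accepts a
    NetworkHandle, a Sequential, a list of layers, or a list of (kernel,
    stride) pairs.
    """
    if isinstance(obj, NetworkHandle):
        obj = obj.net
    if isinstance(obj, nn.Sequential):
        geoms = []
        for lay in obj.layers:
            geoms.extend(lay.geometry())
    else:
        geoms = []
        for item in obj:
            if isinstance(item, nn.Layer):
                geoms.extend(item.geometry())
            else:
                k, s = item
                geoms.append((int(k), int(s)))
    rf, jump = 1, 1
    for k, s in geoms:
        rf += (k - 1) * jump
        jump *= s
    return rf, jump


def count_parameters(handle, include_head: bool = True) -> int:
    """Exact count of trainable scalars (weights, biases, BN scale/shift)."""
    net = handle.net if isinstance(handle, NetworkHandle) else handle
    layers = list(net.layers)
    if not include_head:
        # Drop the trailing GAP + FC classification head (and softmax).
        while layers and isinstance(layers[-1], (nn.Softmax, nn.Dense,
                                                 nn.GlobalAvgPool)):
            layers.pop()
    return sum(p.size for lay in layers for p in lay.params())


# ---------------------------------------------------------------------------
# Conversion to whole-image classifiers

def _head_layers(patch_net: nn.Sequential):
    """Locate the GAP + FC (+ softmax) head of a patch classifier."""
    layers = patch_net.layers
    if not (len(layers) >= 3 and isinstance(layers[-1], nn.Softmax)
            and isinstance(layers[-2], nn.Dense)
            and isinstance(layers[-3], nn.GlobalAvgPool)):
        raise SpecError("patch network lacks the expected GAP+FC head")
    return layers[:-3], layers[-2]


def _heatmap_conv_from_head(fc: nn.Dense, randomize: bool, rng) -> nn.Conv2d:
    """A 1x1 convolution reducing trunk channels to c patch classes; by
    default its weights are the transposed FC head weights."""
    in_ch, c = fc.in_features, fc.out_features
    conv = nn.Conv2d(in_ch, c, 1, 1, "same", bias=True, rng=rng, name="heatmap.conv")
    if not randomize:
        conv.w.data[...] = fc.w.data.T.reshape(c, in_ch, 1, 1)
        conv.b.data[...] = fc.b.data
    return conv


def to_whole_image(patch_handle: NetworkHandle, top: TopSpec,
                   image_size: tuple[int, int] | None = None,
                   seed: int = 100) -> NetworkHandle:
    """Convert a trained patch classifier into a whole-image classifier.

    The GAP+FC head is removed. Depending on the top variant, a heatmap
    (1x1 conv initialized from the head weights, then ReLU or per-cell
    softmax) is inserted, followed by convolutional top blocks with a
    GAP + d-way head, or by max-pool + two FC layers with a shortcut. Trunk
    weights are shared with (not copied from) the source patch classifier.
    """
    rng = np.random.default_rng(seed)
    trunk, fc = _head_layers(patch_handle.net)
    d = top.n_image_classes
    layers: list[nn.Layer] = list(trunk)
    source_count = len(layers)
    ch = patch_handle.trunk_channels

    if top.variant in ("heatmap_then_conv_blocks", "heatmap_maxpool_fc_shortcut"):
        layers.append(_heatmap_conv_from_head(
            fc, randomize=not top.init_heatmap_from_head, rng=rng))
        layers.append(nn.ChannelSoftmax() if top.heatmap_activation == "softmax"
                      else nn.ReLU())
        ch = fc.out_features

    if top.variant == "heatmap_maxpool_fc_shortcut":
        if image_size is None:
            raise SpecError("FC-top variant needs the whole-image size to size "
                            "its flattened input")
        probe = np.zeros((1, patch_handle.net.layers[0].in_ch
                          if isinstance(patch_handle.net.layers[0], nn.Conv2d)
                          else 1, image_size[0], image_size[1]), dtype=np.float32)
        feat = nn.Sequential(layers).forward(probe, train=False)
        layers.append(nn.MaxPool2d(top.pool_size, top.pool_size, name="top.pool"))
        pooled_h = feat.shape[2] // top.pool_size
        pooled_w = feat.shape[3] // top.pool_size
        if pooled_h < 1 or pooled_w < 1:
            raise SpecError("pool size larger than the heatmap grid")
        layers.append(nn.Flatten())
        layers.append(nn.FcTopShortcut(ch * pooled_h * pooled_w,
                                       top.fc_sizes[0], top.fc_sizes[1], d,
                                       rng=rng))
    else:
        for bi, block in enumerate(top.top_blocks):
            blayers, ch = _block_layers(block, ch, rng, f"top{bi}")
            layers.extend(blayers)
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(ch, d, rng=rng, name="top.fc"))
    layers.append(nn.Softmax())
    net = nn.Sequential(layers)
    return NetworkHandle(net=net, kind="whole_image", n_classes=d,
                         input_size=None, provenance="converted",
                         source_layer_count=source_count,
                         trunk_channels=ch, spec=top)


# ---------------------------------------------------------------------------
# Heatmaps

def _grid_conventions(image_shape, rf, stride):
    h, w = image_shape
    same = (-(-h // stride), -(-w // stride))
    valid = ((h - rf) // stride + 1 if h >= rf else 0,
             (w - rf) // stride + 1 if w >= rf else 0)
    return same, valid


def heatmap_of(image: np.ndarray, patch_handle: NetworkHandle,
               activation: str = "softmax") -> Heatmap:
    """Apply the patch classifier fully convolutionally to a whole image.

    The trunk runs on the full image and the head FC is applied as a 1x1
    convolution at every grid cell, giving the u x v x c heatmap.
    """
    image = np.asarray(image, dtype=np.float32)
    rf, stride = receptive_field(
        nn.Sequential(_head_layers(patch_handle.net)[0]))
    if image.shape[0] < rf or image.shape[1] < rf:
        raise SpecError(f"image {image.shape} smaller than the receptive "
                        f"field {rf}")
    trunk, fc = _head_layers(patch_handle.net)
    x = image[None, None]
    feat = nn.Sequential(trunk).forward(x, train=False)
    conv = _heatmap_conv_from_head(fc, randomize=False,
                                   rng=np.random.default_rng(0))
    scores = conv.forward(feat, train=False)
    if activation == "softmax":
        grid = nn.ChannelSoftmax().forward(scores)
    elif activation == "relu":
        grid = np.maximum(scores, 0)
    else:
        raise SpecError(f"unknown activation {activation!r}")
    same, valid = _grid_conventions(image.shape, rf, stride)
    return Heatmap(grid=np.ascontiguousarray(grid[0].transpose(1, 2, 0)),
                   activation_kind=activation, stride=stride,
                   receptive_field=rf, grid_same_padding=same,
                   grid_valid_padding=valid)


def sliding_window_reference(image: np.ndarray, patch_handle: NetworkHandle,
                             stride: int | None = None,
                             batch: int = 256) -> Heatmap:
    """Brute-force oracle: crop every stride-aligned patch, run the full
    patch classifier on each, and assemble the grid. For a valid-padding
    trunk this must equal `heatmap_of` elementwise."""
    image = np.asarray(image, dtype=np.float32)
    rf, net_stride = receptive_field(
        nn.Sequential(_head_layers(patch_handle.net)[0]))
    stride = stride or net_stride
    if image.shape[0] < rf or image.shape[1] < rf:
        raise SpecError(f"image {image.shape} smaller than the receptive "
                        f"field {rf}")
    u = (image.shape[0] - rf) // stride + 1
    v = (image.shape[1] - rf) // stride + 1
    crops = np.empty((u * v, 1, rf, rf), dtype=np.float32)
    idx = 0
    for i in range(u):
        for j in range(v):
            crops[idx, 0] = image[i * stride:i * stride + rf,
                                  j * stride:j * stride + rf]
            idx += 1
    c = patch_handle.n_classes
    out = np.empty((u * v, c), dtype=np.float32)
    for k in range(0, u * v, batch):
        out[k:k + batch] = patch_handle.net.forward(crops[k:k + batch],
                                                    train=False)
    same, valid = _grid_conventions(image.shape, rf, stride)
    return Heatmap(grid=out.reshape(u, v, c), activation_kind="softmax",
                   stride=stride, receptive_field=rf,
                   grid_same_padding=same, grid_valid_padding=valid)


def random_valid_trunk(rng: np.random.Generator,
                       n_patch_classes: int = N_PATCH_CLASSES) -> NetworkHandle:
    """A random valid-padding toy patch classifier whose trunk collapses its
    own receptive field to a 1x1 feature map (so patch output == heatmap
    cell). Used by the fully-convolutional-vs-sliding-window equivalence
    suite."""
    n_blocks = int(rng.integers(2, 4))
    layers: list[nn.Layer] = []
    ch = 1
    for b in range(n_blocks):
        width = int(rng.integers(4, 9))
        k = int(rng.choice([3, 5]))
        layers.append(nn.Conv2d(ch, width, k, 1, "valid", rng=rng,
                                name=f"t{b}.conv"))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2d(2, 2, name=f"t{b}.pool"))
        ch = width
    # Input size that reduces to exactly 1x1 under valid padding: walk the
    # chain backwards from an output of 1.
    size = 1
    for lay in reversed(layers):
        for k, s in reversed(lay.geometry()):
            size = (size - 1) * s + k
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(ch, n_patch_classes, rng=rng, name="head.fc"))
    layers.append(nn.Softmax())
    spec = BackboneSpec(blocks=[BlockSpec("vgg", (ch, 1))], input_size=size,
                        n_patch_classes=n_patch_classes, padding="valid",
                        name="toy-valid")
    return NetworkHandle(net=nn.Sequential(layers), kind="patch",
                         n_classes=n_patch_classes, input_size=size,
                         provenance="random init", trunk_channels=ch,
                         spec=spec)


# ---------------------------------------------------------------------------
# Spec serialization (YAML grammar strings)

def backbone_to_dict(spec: BackboneSpec) -> dict:
    return {"name": spec.name, "input_size": spec.input_size,
            "n_patch_classes": spec.n_patch_classes,
            "in_channels": spec.in_channels, "padding": spec.padding,
            "stem": spec.stem,
            "blocks": [{"grammar": b.grammar(), "batch_norm": b.batch_norm,
                        "stride": b.stride} for b in spec.blocks]}


def backbone_from_dict(d: dict) -> BackboneSpec:
    blocks = []
    for bd in d["blocks"]:
        b = BlockSpec.parse(bd["grammar"], batch_norm=bd.get("batch_norm"))
        b.stride = bd.get("stride", 2)
        blocks.append(b)
    return BackboneSpec(blocks=blocks, input_size=d.get("input_size", 224),
                        n_patch_classes=d.get("n_patch_classes", N_PATCH_CLASSES),
                        in_channels=d.get("in_channels", 1),
                        padding=d.get("padding", "same"),
                        stem=d.get("stem"), name=d.get("name", "custom"))


def save_weights(net: nn.Sequential, path):
    arrays = {f"p{i}": p.data for i, p in enumerate(net.params())}
    bn_state = {}
    for i, lay in enumerate(net.leaf_layers()):
        if isinstance(lay, nn.BatchNorm2d):
            bn_state[f"bn{i}.mean"] = lay.running_mean
            bn_state[f"bn{i}.var"] = lay.running_var
    np.savez(path, **arrays, **bn_state)


def load_weights(net: nn.Sequential, source):
    data = source if isinstance(source, dict) else np.load(source)
    for i, p in enumerate(net.params()):
        p.data[...] = data[f"p{i}"]
    for i, lay in enumerate(net.leaf_layers()):
        if isinstance(lay, nn.BatchNorm2d) and f"bn{i}.mean" in data:
            lay.running_mean[...] = data[f"bn{i}.mean"]
            lay.running_var[...] = data[f"bn{i}.var"]
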