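"""Pipeline configuration.

A flat dataclass of every tunable stage parameter, serializable to and from
YAML/JSON files using dotted section keys (``clahe.blocks``,
``ransac.eps``, ...).  Defaults are the package defaults documented in each
stage module.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ParameterError

# dotted config key -> dataclass attribute
_KEYMAP = {
    "margins.floor_fraction": "margins_floor_fraction",
    "connectivity": "connectivity",
    "clahe.blocks": "clahe_blocks",
    "clahe.clip_limit": "clahe_clip_limit",
    "median.window": "median_window",
    "edge.presmooth_sigma": "edge_presmooth_sigma",
    "edge.kernel": "edge_kernel",
    "skin.band_px": "skin_band_px",
    "candidates.height_fraction": "candidates_height_fraction",
    "hough.vote_threshold": "hough_vote_threshold",
    "hough.min_length": "hough_min_length",
    "hough.max_gap": "hough_max_gap",
    "chain.angle_tol": "chain_angle_tol",
    "chain.gap_tol": "chain_gap_tol",
    "ransac.n": "ransac_n",
    "ransac.eps": "ransac_eps",
    "ransac.K": "ransac_K",
    "ransac.refit": "ransac_refit",
    "seed": "seed",
    "verbosity": "verbosity",
}


@dataclass
class PipelineConfig:
    margins_floor_fraction: float = 0.02
    connectivity: int = 8
    clahe_blocks: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 0.01
    median_window: int = 3
    edge_presmooth_sigma: float = 1.0
    edge_kernel: list | None = None  # optional 3x3 override of the oblique kernel
    skin_band_px: int = 5
    candidates_height_fraction: float = 0.5
    hough_vote_threshold: int = 30
    hough_min_length: int = 20
    hough_max_gap: int = 5
    chain_angle_tol: float = 10.0
    chain_gap_tol: float = 20.0
    ransac_n: int = 3
    # the binarized edge band at the default blur is ~8 px wide; the inlier
    # tolerance must span its half-width so the consensus refit averages the
    # band symmetrically instead of sliding inside it
    ransac_eps: float = 8.0
    ransac_K: int = 1000
    ransac_refit: bool = True
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.connectivity != 8:
            raise ParameterError("only 8-connectivity labeling is supported")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ParameterError("median.window must be odd and >= 3")
        if self.clahe_clip_limit <= 0:
            raise ParameterError("clahe.clip_limit must be > 0")
        self.clahe_blocks = (int(self.clahe_blocks[0]), int(self.clahe_blocks[1]))

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        kwargs = {}
        for key, value in mapping.items():
            attr = _KEYMAP.get(key, key if key in {f.name for f in fields(cls)} else None)
            if attr is None:
                raise ParameterError(f"unknown config key {key!r}")
            kwargs[attr] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        inv = {attr: key for key, attr in _KEYMAP.items()}
        data = {inv[k]: v for k, v in asdict(self).items()}
        data["clahe.blocks"] = list(self.clahe_blocks)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
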