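"""Run configuration: structured-text (YAML) configs with strict parsing.

A :class:`RunConfig` fully determines a run: mode, lengths, sampler settings,
prior parameters, conditioner stack and output paths.  Unknown keys are
rejected so that typos fail loudly, and a parsed config round-trips losslessly
through :meth:`RunConfig.to_dict`.  Clamp masks use 1-based inclusive
``chain:start-end`` strings; shape clouds are referenced by file path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import conditioners as cond_mod
from .diffusion import SamplerSettings
from .prior import PolymerPrior
from .schedule import DiffusionSchedule
from .structures import BackboneStructure, PointCloudShape, read_pdb
from .symmetry import make_symmetry_group

_MODES = ("sample", "train", "analyze")


@dataclass
class RunConfig:
    mode: str = "sample"
    lengths: list[int] = field(default_factory=lambda: [100])
    n_samples: int = 1
    # sampler
    lambda_: float = 1.0
    psi: int = 0
    n_steps: int = 200
    seed: int = 0
    # prior
    r0: float = 2.0
    nu: float = 0.4
    centroid_sigma: float = 0.0
    # schedule
    logsnr_max: float = 10.0
    logsnr_min: float = -10.0
    # denoiser / training
    weights_path: str | None = None
    n_epochs: int = 8
    n_train_structures: int = 200
    train_length_range: list[int] = field(default_factory=lambda: [30, 80])
    # conditioners: list of {type: ..., <params>}
    conditioners: list[dict] = field(default_factory=list)
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    # -- (de)serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- factories -------------------------------------------------------------

    def schedule(self) -> DiffusionSchedule:
        return DiffusionSchedule(self.n_steps, self.logsnr_max, self.logsnr_min)

    def sampler_settings(self, seed: int | None = None) -> SamplerSettings:
        return SamplerSettings(lambda_=self.lambda_, psi=self.psi,
                               n_steps=self.n_steps,
                               seed=self.seed if seed is None else seed)

    def prior(self, n_residues: int) -> PolymerPrior:
        return PolymerPrior(n_residues, self.r0, self.nu, self.centroid_sigma)


def parse_clamp_mask(spec: str, structure: BackboneStructure) -> np.ndarray:
    """Parse 'chain:start-end[,chain:start-end...]' (1-based, inclusive)."""
    mask = np.zeros(structure.n_residues, dtype=bool)
    slices = structure.chain_slices()
    for part in spec.split(","):
        part = part.strip()
        if ":" not in part:
            raise ValueError(f"bad clamp range {part!r} (expected chain:start-end)")
        chain, rng = part.split(":", 1)
        if chain not in slices:
            raise ValueError(f"clamp references unknown chain {chain!r}")
        if "-" in rng:
            lo, hi = (int(v) for v in rng.split("-", 1))
        else:
            lo = hi = int(rng)
        sl = slices[chain]
        res_ids = structure.res_ids[sl]
        sel = (res_ids >= lo) & (res_ids <= hi)
        if not sel.any():
            raise ValueError(f"clamp range {part!r} selects no residues")
        idx = np.arange(sl.start, sl.stop)[sel]
        mask[idx] = True
    return mask


def build_conditioner_stack(blocks: list[dict], prior_proto: PolymerPrior,
                            schedule: DiffusionSchedule, seed: int = 0,
                            base_dir: Path | None = None) -> list:
    """Instantiate a conditioner stack from config blocks.

    Each block is a mapping with a ``type`` key in {symmetry, substructure,
    distance, shape, classifier} plus that conditioner's parameters.
    """
    base_dir = Path(base_dir) if base_dir else Path(".")
    stack = []
    for k, block in enumerate(blocks):
        block = dict(block)
        kind = block.pop("type", None)
        try:
            if kind == "symmetry":
                group = make_symmetry_group(block.pop("group"))
                stack.append(cond_mod.make_symmetry_conditioner(
                    group, soft_weight=float(block.pop("soft_weight", 0.0))))
            elif kind == "substructure":
                ref = read_pdb(base_dir / block.pop("reference"))
                mask = parse_clamp_mask(block.pop("clamp"), ref)
                stack.append(cond_mod.make_substructure_conditioner(
                    ref, mask, prior_proto, schedule, noise_seed=seed))
            elif kind == "distance":
                stack.append(cond_mod.make_distance_conditioner(
                    block.pop("pairs"), block.pop("targets"),
                    float(block.pop("force_constant", 1.0))))
            elif kind == "shape":
                cloud = PointCloudShape.from_file(base_dir / block.pop("cloud"))
                stack.append(cond_mod.make_shape_conditioner(
                    cloud, epsilon=float(block.pop("epsilon", 1.0)),
                    weight=float(block.pop("weight", 1.0))))
            elif kind == "classifier":
                builtin = block.pop("builtin", "helix_content")
                if builtin != "helix_content":
                    raise ValueError(f"unknown builtin classifier {builtin!r}")
                stack.append(cond_mod.make_classifier_conditioner(
                    cond_mod.helix_content_log_prob,
                    guidance_scale=float(block.pop("guidance_scale", 1.0))))
            else:
                raise ValueError(f"unknown conditioner type {kind!r}")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid conditioner block #{k} ({kind!r}): {exc}") from exc
        if block:
            raise ValueError(f"conditioner block #{k} ({kind}): "
                             f"unknown parameters {sorted(block)}")
    return stack
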