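"""Flat key-value run configuration with lossless file round-trips.

The config file format is one ``key = value`` pair per line, ``#`` comments
allowed.  Command-line flags override file values, which override the
defaults below.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

from .dynamics import ModelParams
from .experiment import ExperimentGrid

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: model, grid and plumbing."""

    # model
    pn: float = 0.5
    pa: float = 0.5
    pr: float = 0.01
    n: int = 50
    timesteps: int = 1000
    variant: str = "one_step"
    p_assoc_init: float = 0.1
    p_avoid_init: float = 0.1
    classification_rule: str = "count"
    walktrap_steps: int = 4
    random_assoc_prob: Optional[float] = None
    # grid
    pa_values: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    pn_values: tuple = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    pr_values: tuple = (0.001, 0.01, 0.05)
    variants: tuple = ("one_step", "two_step")
    replicates: int = 100
    base_seed: int = 0
    # plumbing
    outdir: str = "avoidnet_out"
    burn_in: int = 0
    log_level: str = "INFO"

    def model_params(self) -> ModelParams:
        return ModelParams(
            pn=self.pn, pa=self.pa, pr=self.pr, n=self.n,
            timesteps=self.timesteps, variant=self.variant,
            p_assoc_init=self.p_assoc_init, p_avoid_init=self.p_avoid_init,
            classification_rule=self.classification_rule,
            walktrap_steps=self.walktrap_steps,
            random_assoc_prob=self.random_assoc_prob,
        )

    def grid(self) -> ExperimentGrid:
        return ExperimentGrid(
            pa_values=self.pa_values, pn_values=self.pn_values,
            pr_values=self.pr_values, variants=self.variants,
            replicates=self.replicates, base_seed=self.base_seed,
        )


def _format(value) -> str:
    if isinstance(value, tuple):
        return ",".join(_format(v) for v in value)
    if value is None:
        return "none"
    return str(value)


def _parse(name: str, text: str):
    text = text.strip()
    hints = {f.name: f for f in fields(RunConfig)}
    if name not in hints:
        raise ValueError(f"unknown config key {name!r}")
    default = getattr(RunConfig(), name)
    if isinstance(default, tuple):
        parts = [p for p in text.split(",") if p]
        if name == "variants":
            return tuple(parts)
        return tuple(float(p) for p in parts)
    if text.lower() == "none":
        return None
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float) or name == "random_assoc_prob":
        return float(text)
    return text


def save_config(cfg: RunConfig, path) -> None:
    lines = [f"{k} = {_format(v)}" for k, v in asdict(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> RunConfig:
    values = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        key = key.strip()
        values[key] = _parse(key, val)
    return RunConfig(**values)
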