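"""Run configuration for the age-inference pipeline.

All tunables live in one flat dataclass; a config file (YAML, or plain
``section.key = value`` lines) can override any field. Every run emits
the resolved configuration in its metadata so results are reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

# file keys use dotted section names; map them onto dataclass fields
_KEY_MAP = {
    "similarity.fraction": "similarity_fraction",
    "similarity.correlation": "similarity_correlation",
    "diffusion.w": "diffusion_w",
    "diffusion.tol": "diffusion_tol",
    "diffusion.max_iter": "diffusion_max_iter",
    "diffusion.mode": "diffusion_mode",
    "clockacc.censor": "clockacc_censor",
    "clockacc.censor_quantile": "clockacc_censor_quantile",
    "rank.bulk_reverse": "bulk_reverse",
    "iteration.z_cutoff": "z_cutoff",
    "iteration.convergence_rho": "convergence_rho",
    "iteration.max_outer_iter": "max_outer_iter",
    "iteration.signed_expansion": "signed_expansion",
    "iteration.resolve_nnls": "resolve_nnls_in_loop",
    "dispersion.method": "dispersion_method",
    "qc.min_fragments": "min_fragments",
}


@dataclass
class EpiTraceConfig:
    """Defaults for one full run; see docs/methods.md for rationale."""

    similarity_fraction: float = 0.05       # top-dispersion peak fraction
    similarity_correlation: str = "pearson"  # or "spearman"
    dispersion_method: str = "fano"          # variance/mean; or "cv"
    diffusion_w: float = 0.5                 # source weight in the relaxation
    diffusion_tol: float = 1e-4              # max|Δx| stopping threshold
    diffusion_max_iter: int = 100
    diffusion_mode: str = "reaction"         # source-injected; or "pure" averaging
    clockacc_censor: bool = False            # winsorize counts before open-test
    clockacc_censor_quantile: float = 0.95
    bulk_reverse: bool = True                # bulk mode reports 1 - rank
    z_cutoff: float = 3.0                    # reference expansion (2.5 also common)
    signed_expansion: bool = False           # admit negative-r peaks if True
    convergence_rho: float = 0.99            # Spearman rho between outer iterations
    max_outer_iter: int = 5
    resolve_nnls_in_loop: bool = False       # re-run NNLS inside diffusion loop
    min_fragments: int = 0                   # QC filter, off by default

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "EpiTraceConfig":
        """Load overrides from YAML or flat ``a.b = c`` key-value lines."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = _parse_flat(text)
        flat = _flatten(data)
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for key, value in flat.items():
            field_name = _KEY_MAP.get(key, key.replace(".", "_"))
            if field_name not in valid:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[field_name] = value
        return cls(**kwargs)


def _parse_flat(text: str) -> dict:
    out: dict = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line: {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = yaml.safe_load(value)
    return out


def _flatten(data: dict, prefix: str = "") -> dict:
    flat: dict = {}
    for key, value in data.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{full}."))
        else:
            flat[full] = value
    return flat
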