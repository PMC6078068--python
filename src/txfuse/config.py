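"""Run configuration shared by the library and the CLI.

Defaults anchor on the merging protocol this package implements: Markov
clustering inflation 4 (fine-grained groups so isoforms resist collapsing),
clustering k-mer 31, sketch k-mer 51 with 5,000 hashes, and a 250 +/- 50 bp
insert model for pair-order scoring.  Configuration can come from a flat
``key=value`` file, with command-line flags winning over file values; the
effective configuration is echoed verbatim into every run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    k_cluster: int = 31
    min_similarity: float = 0.1
    inflation: float = 4.0
    seed_k: int = 31
    sketch_k: int = 51
    num_hashes: int = 5000
    insert_mean: int = 250
    insert_sd: int = 50
    seed: int = 0
    threads: int = 1
    out_dir: str | None = None

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load flat ``key=value`` lines ('#' comments allowed); overrides win."""
        values: dict = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            if key == "out_dir":
                values[key] = raw
            elif key in ("min_similarity", "inflation"):
                values[key] = float(raw)
            else:
                values[key] = int(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def override(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
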