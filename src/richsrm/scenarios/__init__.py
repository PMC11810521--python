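"""Shipped scenario YAML files for the synthetic-site presets."""

from importlib import resources
from pathlib import Path


def scenario_path(name: str) -> Path:
    """Filesystem path of a shipped scenario YAML (e.g. ``coastal_like``)."""
    return Path(resources.files(__name__) / f"{name}.yaml")
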