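"""Access to the packaged defaults file (data/defaults.toml)."""

from __future__ import annotations

import tomllib
from functools import lru_cache
from importlib import resources

__all__ = ["defaults", "default"]


@lru_cache(maxsize=1)
def defaults() -> dict:
    """The parsed defaults table (cached)."""
    ref = resources.files("halopbpk.data") / "defaults.toml"
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def default(*keys, override=None):
    """Dotted lookup into the defaults, e.g. default('solver', 'rtol');
    a non-None `override` wins."""
    if override is not None:
        return override
    node = defaults()
    for k in keys:
        node = node[k]
    return node
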