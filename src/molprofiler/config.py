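"""Access to the editable parameter tables shipped under ``molprofiler/data``.

Every numeric table the descriptor and curation layers depend on (PEOE
electronegativity polynomials, vdW/covalent radii, logP/TPSA contribution
tables, logD/logS surrogate coefficients, reactive-group SMARTS, salt and
solvent fragment lists, generator fragment sets) lives in a YAML file so it
can be inspected or replaced without touching code.
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml


class ConfigurationError(RuntimeError):
    """A parameter table is missing an entry required for the input at hand."""


@functools.lru_cache(maxsize=None)
def load(name: str) -> dict:
    """Load ``molprofiler/data/<name>.yaml`` (cached)."""
    ref = resources.files("molprofiler.data").joinpath(f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)
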