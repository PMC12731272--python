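"""Built-in worked-example models.

``fig1`` is the five-taxon community used throughout the documentation:
taxon ``a`` feeds ``b`` (f2, f4), ``b`` feeds ``d`` and ``e`` (f3), ``d``
and ``e`` close the loop (f1, f4), ``c`` produces toxin ``t1`` to which
``a`` is sensitive.  The BARS three-strain fixtures encode the
Bacillota A/R/S community in which all strains grow independently and the
structure arises purely from inhibition: variant ``a`` has no toxin,
variant ``b`` has A inhibiting both S and R, variant ``c`` only S.
"""

from __future__ import annotations

from importlib import resources as _resources

from .errors import UnknownLabelError
from .model import CRTModel, read_model

FIXTURE_NAMES = ("fig1", "bars_a", "bars_b", "bars_c")


def fixture(name: str) -> CRTModel:
    """Load a built-in model by name (``fig1``, ``bars_a``, ``bars_b``,
    ``bars_c``).  The TSV files under ``cotox/data`` double as format
    documentation."""
    if name not in FIXTURE_NAMES:
        raise UnknownLabelError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    text = (_resources.files("cotox") / "data" / f"{name}.tsv").read_text()
    return read_model(text, format="tsv")
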