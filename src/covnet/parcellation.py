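"""Cortical parcellation region lists.

The default parcellation is the Desikan-Killiany atlas: 68 cortical
regions, 34 per hemisphere, named ``lh_<region>`` / ``rh_<region>``.
"""
from __future__ import annotations

from importlib import resources

__all__ = ["desikan_killiany_68", "load_parcellation"]


def desikan_killiany_68() -> list[str]:
    """Return the 68 Desikan-Killiany region names (lh then rh, each sorted)."""
    text = (
        resources.files("covnet.data").joinpath("desikan_killiany_68.txt").read_text()
    )
    return text.split()


def load_parcellation(path) -> list[str]:
    """Read a parcellation file: one region name per line, blanks ignored.

    Raises ``ValueError`` on duplicate region names.
    """
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate region names in parcellation: {sorted(dupes)}")
    return names
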