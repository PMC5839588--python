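"""Packaged survey tables: Lake Averno water column, 17 June 2015.

Verbatim transcriptions of the published depth profiles (0-34 m every 2 m)
of water chemistry and dissolved-gas partial pressures.
"""

from __future__ import annotations

from importlib import resources

from ..profile import (
    LakeProfile,
    align_profiles,
    read_chemistry_table,
    read_gas_table,
)


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def averno_chemistry_path():
    """Path-like handle on the packaged chemistry table (CSV)."""
    return _path("averno_table1.csv")


def averno_gas_path():
    """Path-like handle on the packaged dissolved-gas table (CSV)."""
    return _path("averno_table2.csv")


def load_averno_chemistry():
    with resources.as_file(averno_chemistry_path()) as p:
        return read_chemistry_table(p)


def load_averno_gas():
    with resources.as_file(averno_gas_path()) as p:
        return read_gas_table(p)


def load_averno_2015() -> LakeProfile:
    """The joined 2015 Averno profile (18 depths, 0-34 m)."""
    return align_profiles(load_averno_chemistry(), load_averno_gas())
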