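"""Access to the bundled CVX value sets (category <-> vaccine codes)."""
from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Dict, FrozenSet

import yaml

_DEFAULT_PATH = Path(__file__).parent / "data" / "valuesets.yaml"


@lru_cache(maxsize=None)
def _load(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def category_cvx(path=None) -> Dict[str, FrozenSet[str]]:
    """CVX codes counting toward each category slug's series."""
    doc = _load(str(path or _DEFAULT_PATH))
    return {slug: frozenset(codes) for slug, codes in doc["category_cvx"].items()}


def product_cvx(path=None) -> Dict[str, str]:
    """CVX code recorded for a dose of each named vaccine product."""
    doc = _load(str(path or _DEFAULT_PATH))
    return dict(doc["product_cvx"])
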