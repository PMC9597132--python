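"""Item scheme for the 20-item Toronto Alexithymia Scale.

The TAS-20 has a fixed item set with three intended subscales —
difficulty identifying feelings (DIF), difficulty describing feelings
(DDF), and externally oriented thinking (EOT) — and five reverse-worded
items.  Competing measurement models reassign the same 20 items to
different partitions; all partitions live in one configuration file so
no item list is hidden in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["ItemScheme", "default_scheme", "item_label"]


def item_label(number: int) -> str:
    """Canonical label for an item position, e.g. ``3 -> 'item03'``."""
    return f"item{number:02d}"


@dataclass(frozen=True)
class ItemScheme:
    """Fixed item set, keying, and named item->factor partitions.

    Parameters
    ----------
    n_items
        Number of items (20 for the TAS-20).
    item_labels
        Ordered unique labels, ``item01`` .. ``item20``.
    negative_keyed
        The reverse-worded items (exactly five for the TAS-20).
    factor_assignments
        Map from partition name (e.g. ``three_factor``) to an ordered
        map factor name -> tuple of item labels.  Each partition covers
        every item exactly once; bifactor/method overlays are expressed
        at the model level, not here.
    """

    n_items: int
    item_labels: tuple[str, ...]
    negative_keyed: frozenset[str]
    factor_assignments: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.item_labels) != self.n_items:
            raise ValueError("item_labels length does not match n_items")
        if len(set(self.item_labels)) != self.n_items:
            raise ValueError("item labels must be unique")
        if not self.negative_keyed <= set(self.item_labels):
            raise ValueError("negative_keyed must be a subset of item_labels")
        if self.n_items == 20 and len(self.negative_keyed) != 5:
            raise ValueError("the TAS-20 has exactly five reverse-keyed items")
        for name, partition in self.factor_assignments.items():
            covered = [it for items in partition.values() for it in items]
            if sorted(covered) != sorted(self.item_labels):
                raise ValueError(f"partition {name!r} does not cover all items exactly once")

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.item_labels)}

    def partition(self, name: str) -> dict[str, tuple[str, ...]]:
        try:
            return self.factor_assignments[name]
        except KeyError:
            raise KeyError(
                f"unknown partition {name!r}; available: {sorted(self.factor_assignments)}"
            ) from None

    def primary_factor(self, partition_name: str) -> dict[str, str]:
        """Map item label -> its factor within one partition."""
        out: dict[str, str] = {}
        for factor, items in self.partition(partition_name).items():
            for it in items:
                out[it] = factor
        return out


def _load_config() -> dict:
    with resources.files("tas_masem.data").joinpath("tas20.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def default_scheme() -> ItemScheme:
    """The TAS-20 scheme shipped with the package (data/tas20.yaml)."""
    cfg = _load_config()
    n = int(cfg["n_items"])
    labels = tuple(item_label(i) for i in range(1, n + 1))
    neg = frozenset(item_label(i) for i in cfg["negative_keyed"])
    assignments = {
        pname: {
            factor: tuple(item_label(i) for i in items)
            for factor, items in partition.items()
        }
        for pname, partition in cfg["partitions"].items()
    }
    return ItemScheme(
        n_items=n,
        item_labels=labels,
        negative_keyed=neg,
        factor_assignments=assignments,
    )
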