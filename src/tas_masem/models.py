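"""Catalog of competing TAS-20 measurement models.

Each model is a declarative constraint set over the standardized factor
solution: an item->factor partition, free or orthogonal factor
correlations, and optional overlays (a general factor over all items, a
nested method factor over the reverse-keyed items, or free residual
correlations among them).  Factors have unit variance and all assigned
loadings free, so a model's degrees of freedom are

    df = p(p-1)/2  -  (#free loadings + #factor correlations + #residual correlations),

which is audited against the published fit table model by model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .items import ItemScheme, default_scheme, _load_config

__all__ = ["ModelSpec", "ModelCatalog", "build_catalog"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative specification of one measurement model."""

    name: str
    description: str
    factors: dict[str, tuple[str, ...]]        # content factor -> item labels
    correlated: bool                            # free correlations among content factors
    general_factor: bool = False                # orthogonal factor over all items
    method_items: tuple[str, ...] = ()          # orthogonal method factor over these items
    residual_pairs: tuple[tuple[str, str], ...] = ()   # free residual correlations
    kind: str = "measurement"                   # or "independence" / "saturated"

    def __post_init__(self) -> None:
        if self.kind != "measurement":
            return
        items = sorted(it for its in self.factors.values() for it in its)
        if self.general_factor:
            pass  # general factor loads on every item in addition to the partition
        if len(items) != len(set(items)):
            raise ValueError(f"model {self.name}: partition assigns an item twice")
        pairs = [tuple(sorted(p)) for p in self.residual_pairs]
        if len(pairs) != len(set(pairs)):
            raise ValueError(f"model {self.name}: duplicate residual-correlation pair")

    def n_free_parameters(self, n_items: int) -> int:
        if self.kind == "independence":
            return 0
        if self.kind == "saturated":
            return n_items * (n_items - 1) // 2
        q = sum(len(its) for its in self.factors.values())
        if self.general_factor:
            q += n_items
        q += len(self.method_items)
        if self.correlated:
            f = len(self.factors)
            q += f * (f - 1) // 2
        q += len(self.residual_pairs)
        return q

    def degrees_of_freedom(self, n_items: int) -> int:
        return n_items * (n_items - 1) // 2 - self.n_free_parameters(n_items)


@dataclass(frozen=True)
class ModelCatalog:
    specs: dict[str, ModelSpec] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ModelSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(f"unknown model {name!r}; available: {list(self.specs)}") from None

    def __iter__(self):
        return iter(self.specs.values())

    def names(self, *, measurement_only: bool = True) -> list[str]:
        return [s.name for s in self if not measurement_only or s.kind == "measurement"]

    def df_table(self, n_items: int = 20) -> dict[str, int]:
        return {s.name: s.degrees_of_freedom(n_items) for s in self if s.kind == "measurement"}


def _build_spec(name: str, cfg: dict, scheme: ItemScheme) -> ModelSpec:
    partition = dict(scheme.partition(cfg["partition"]))
    if "drop_specific" in cfg:
        for factor in cfg["drop_specific"]:
            partition.pop(factor)
    neg = tuple(sorted(scheme.negative_keyed))
    method_items: tuple[str, ...] = ()
    if cfg.get("method_factor") == "negative_keyed":
        method_items = neg
    residual_pairs: tuple[tuple[str, str], ...] = ()
    if cfg.get("residual_correlations") == "negative_keyed":
        residual_pairs = tuple(
            (neg[a], neg[b]) for a in range(len(neg)) for b in range(a + 1, len(neg))
        )
    covered = {it for its in partition.values() for it in its}
    if not cfg.get("drop_specific") and covered != set(scheme.item_labels):
        raise ValueError(f"model {name}: partition does not cover all items")
    if not set(method_items) <= set(scheme.item_labels):
        raise ValueError(f"model {name}: method-factor items outside the item set")
    return ModelSpec(
        name=name,
        description=cfg.get("description", name),
        factors=partition,
        correlated=bool(cfg.get("correlated", True)),
        general_factor=bool(cfg.get("general_factor", False)),
        method_items=method_items,
        residual_pairs=residual_pairs,
    )


def build_catalog(scheme: ItemScheme | None = None, *,
                  include_variants: bool = False) -> ModelCatalog:
    """Build the default catalog from the packaged configuration.

    Includes the nine competing measurement models plus ``independence``
    (the null baseline for incremental fit indices) and ``saturated``.
    ``include_variants`` adds the reference-factor bifactor variant 5b.
    """
    scheme = scheme or default_scheme()
    cfg = _load_config()
    specs: dict[str, ModelSpec] = {}
    for name, mcfg in cfg["models"].items():
        specs[name] = _build_spec(name, mcfg, scheme)
    if include_variants:
        for name, mcfg in cfg.get("variants", {}).items():
            specs[name] = _build_spec(name, mcfg, scheme)
    specs["independence"] = ModelSpec(
        name="independence", description="Null model (all correlations zero)",
        factors={}, correlated=False, kind="independence")
    specs["saturated"] = ModelSpec(
        name="saturated", description="Saturated model",
        factors={}, correlated=False, kind="saturated")
    return ModelCatalog(specs=specs)
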