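"""Schema-validated run configuration (YAML) and library export/import.

The config dialect is a nested YAML document with four sections — alleles,
loci, strains and linkage — plus a ``cross`` block naming the parents and
simulation settings and an optional ``inference`` block.  Unknown keys are
rejected before any computation so typos fail loudly.  The bundled strain
library exports to the same dialect, and a round trip through
``export_library``/``load_library`` reproduces the model exactly, so users
can define new alleles by editing the exported file by analogy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .genetics import (
    Allele,
    BINUCLEATE_TETRAD,
    CrossSpec,
    Haplotype,
    Locus,
)
from .strains import StrainLibrary


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LocusCfg(_Strict):
    chromosome: str
    sds: float = Field(ge=0.0, le=1.0)
    position_morgans: Optional[float] = None


class AlleleCfg(_Strict):
    locus: str
    distorter: bool = False
    covers: List[str] = Field(default_factory=list)
    trans_activators: List[str] = Field(default_factory=list)
    pigment: bool = False
    markers: List[str] = Field(default_factory=list)
    killing_efficiency: float = 1.0


class LinkageCfg(_Strict):
    loci: Tuple[str, str]
    r: float = Field(ge=0.0, le=0.5)


class CrossCfg(_Strict):
    parent1: str
    parent2: str
    packaging: str = BINUCLEATE_TETRAD
    n_asci: int = 10_000
    seed: int = 1
    crossover_model: str = "phenomenological"
    name: Optional[str] = None


class InferenceCfg(_Strict):
    ci_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    adjust: str = "fdr_bh"
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)


class RunConfig(_Strict):
    loci: Dict[str, LocusCfg]
    alleles: Dict[str, AlleleCfg]
    strains: Dict[str, Dict[str, str]]
    linkage: List[LinkageCfg] = Field(default_factory=list)
    cross: Optional[CrossCfg] = None
    inference: InferenceCfg = Field(default_factory=InferenceCfg)

    # -- conversion ----------------------------------------------------
    def to_library(self) -> StrainLibrary:
        loci = {
            lid: Locus(
                id=lid,
                chromosome=cfg.chromosome,
                sds_prob=cfg.sds,
                position_morgans=cfg.position_morgans,
            )
            for lid, cfg in self.loci.items()
        }
        alleles = {}
        for aid, cfg in self.alleles.items():
            if cfg.locus not in loci:
                raise ConfigurationError(
                    f"allele {aid!r} references unknown locus {cfg.locus!r}"
                )
            alleles[aid] = Allele(
                id=aid,
                locus_id=cfg.locus,
                distorter_active=cfg.distorter,
                responder_covers=frozenset(cfg.covers),
                trans_activators=frozenset(cfg.trans_activators),
                pigment_functional=cfg.pigment,
                selectable_markers=frozenset(cfg.markers),
                killing_efficiency=cfg.killing_efficiency,
            )
        linkage = {}
        for entry in self.linkage:
            a, b = entry.loci
            for lid in (a, b):
                if lid not in loci:
                    raise ConfigurationError(f"linkage references unknown locus {lid!r}")
            linkage[frozenset((a, b))] = entry.r
        strains = {
            name: Haplotype(strain_id=name, alleles=dict(mapping))
            for name, mapping in self.strains.items()
        }
        return StrainLibrary(loci=loci, alleles=alleles, linkage=linkage, strains=strains)

    def to_cross_spec(self) -> CrossSpec:
        if self.cross is None:
            raise ConfigurationError("config has no 'cross' block")
        from .strains import make_cross

        lib = self.to_library()
        return make_cross(
            lib,
            self.cross.parent1,
            self.cross.parent2,
            n_asci=self.cross.n_asci,
            seed=self.cross.seed,
            packaging=self.cross.packaging,
            name=self.cross.name,
            crossover_model=self.cross.crossover_model,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is not a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from None


def library_to_config(library: StrainLibrary) -> dict:
    """Serialise a strain library to the config dialect (plain dict)."""
    return {
        "loci": {
            l.id: {
                "chromosome": l.chromosome,
                "sds": l.sds_prob,
                **(
                    {"position_morgans": l.position_morgans}
                    if l.position_morgans is not None
                    else {}
                ),
            }
            for l in library.loci.values()
        },
        "alleles": {
            a.id: {
                "locus": a.locus_id,
                **({"distorter": True} if a.distorter_active else {}),
                **({"covers": sorted(a.responder_covers)} if a.responder_covers else {}),
                **(
                    {"trans_activators": sorted(a.trans_activators)}
                    if a.trans_activators
                    else {}
                ),
                **({"pigment": True} if a.pigment_functional else {}),
                **({"markers": sorted(a.selectable_markers)} if a.selectable_markers else {}),
                **(
                    {"killing_efficiency": a.killing_efficiency}
                    if a.killing_efficiency != 1.0
                    else {}
                ),
            }
            for a in library.alleles.values()
        },
        "strains": {
            name: dict(h.alleles) for name, h in library.strains.items()
        },
        "linkage": [
            {"loci": sorted(pair), "r": r} for pair, r in sorted(
                library.linkage.items(), key=lambda kv: sorted(kv[0])
            )
        ],
    }


def export_library(library: StrainLibrary, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(library_to_config(library), sort_keys=True, allow_unicode=True)
    )


def load_library(path: str | Path) -> StrainLibrary:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"library file {path} is not a mapping")
    raw.setdefault("cross", None)
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from None
    return cfg.to_library()
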