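import pytest

from paleodraught.core import (
    Element,
    Fusion,
    Limb,
    OAState,
    PathologyScores,
    Side,
    Specimen,
)
from paleodraught.simulate import HerdConfig, TaphonomyConfig, generate_assemblage


def make_phalanx(
    sid,
    limb=Limb.ANTERIOR,
    pex=1,
    dex=1,
    plip=1,
    oa_prox=OAState.ABSENT,
    oa_dist=OAState.ABSENT,
    individual_id=None,
    side=Side.LEFT,
):
    return Specimen(
        specimen_id=sid,
        element=Element.PHALANX1,
        limb=limb,
        side=side,
        pathology=PathologyScores(pex=pex, dex=dex, plip=plip, oa_prox=oa_prox, oa_dist=oa_dist),
        individual_id=individual_id,
    )


def make_metapodial(
    sid,
    element=Element.METACARPAL,
    fusion=Fusion.FUSED,
    side=Side.LEFT,
    individual_id=None,
    **measurements,
):
    limb = Limb.ANTERIOR if element == Element.METACARPAL else Limb.POSTERIOR
    return Specimen(
        specimen_id=sid,
        element=element,
        limb=limb,
        side=side,
        distal_fusion=fusion,
        measurements=measurements,
        individual_id=individual_id,
    )


@pytest.fixture(scope="session")
def herd200():
    """One shared synthetic assemblage: 200 individuals, default management
    (30% of adult males/castrates worked), default taphonomy."""
    cfg = HerdConfig(n_individuals=200, seed=1)
    assemblage, truth = generate_assemblage(cfg, TaphonomyConfig())
    return cfg, assemblage, truth


@pytest.fixture(scope="session")
def herd_small():
    cfg = HerdConfig(n_individuals=40, seed=5)
    assemblage, truth = generate_assemblage(cfg, TaphonomyConfig())
    return cfg, assemblage, truth
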