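"""Shared phantom study conditions for the acceptance script.

One place defines the lesion phantom used across the recovery studies: a
radially fissured, protruded lesion with a separated subchondral fragment
and sclerotic rim, imaged with 0.4 mm MRI / 0.5 mm CT voxels and additive
noise, under a fixed rigid inter-modality transform.
"""
from capfuse import RigidTransform
from capfuse.phantom import PhantomConfig, angular_extent_for_extents


def lesion_config(seed: int, true_transform: RigidTransform = None,
                  extents_mm: tuple = (14.0, 12.0),
                  ssb_planes: int = 3) -> PhantomConfig:
    base = PhantomConfig(
        fissure_enabled=True,
        protrusion_height_mm=1.5,
        ssb_enabled=True,
        ssb_cleft_planes=ssb_planes,
        sclerosis_enabled=True,
        noise_sd=2.0,
        seed=seed,
        true_transform=true_transform or RigidTransform.identity(),
    )
    av, ah = angular_extent_for_extents(*extents_mm, base)
    return PhantomConfig(**{**base.__dict__, "lesion_angular_extent": (av, ah)})
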