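import pytest

from spinedyn import DendriteRecord, FeatureTrack, ImagingSchedule, MouseDataset


def dataset_from_statuses(
    statuses,
    days=(0, 1, 2),
    mouse_id="m1",
    genotype="WT",
    age_group="adult",
    segment_length_um=None,
):
    """Build a one-dendrite MouseDataset from per-feature status sequences.

    ``statuses`` is a list of sequences, one status string per scheduled
    day (same order as ``days``).
    """
    schedule = ImagingSchedule(tuple(days))
    tracks = [
        FeatureTrack(
            feature_id=f"f{i}",
            dendrite_id="d1",
            status_by_session={d: s for d, s in zip(days, seq)},
        )
        for i, seq in enumerate(statuses)
    ]
    dendrite = DendriteRecord(
        dendrite_id="d1",
        mouse_id=mouse_id,
        tracks=tracks,
        segment_length_um=segment_length_um,
    )
    return MouseDataset(
        mouse_id=mouse_id,
        genotype=genotype,
        age_group=age_group,
        schedule=schedule,
        dendrites=[dendrite],
    )


@pytest.fixture
def make_dataset():
    return dataset_from_statuses
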