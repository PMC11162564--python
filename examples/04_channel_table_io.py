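"""Reading real recordings from delimited channel tables.

Any recording converted to two CSV tables — EMG/ECG at the amplifier rate
and Paw/flow/volume at the ventilator rate, each with a time column in
seconds — can be analysed exactly like a synthetic session.  This example
writes a session to disk, reads it back and aligns it.
"""
import tempfile
from pathlib import Path

from nmcdi import align_session, read_channel_table, write_channel_table
from nmcdi.cli import EMG_DIALECT, VENT_DIALECT
from nmcdi.synthetic import preset_spec, simulate_session

session, _ = simulate_session(preset_spec("clean", seed=1))

with tempfile.TemporaryDirectory() as d:
    emg_path = Path(d) / "emg_channels.csv"
    vent_path = Path(d) / "vent_channels.csv"
    write_channel_table([session.emg_di, session.ecg], emg_path, EMG_DIALECT)
    write_channel_table([session.paw, session.flow, session.volume], vent_path, VENT_DIALECT)

    emg, ecg = read_channel_table(emg_path, EMG_DIALECT)
    paw, flow, volume = read_channel_table(vent_path, VENT_DIALECT)
    loaded = align_session(emg, ecg, paw, flow, volume, session.peep_schedule)

print(f"EMG: {loaded.emg_di.n} samples at {loaded.emg_di.rate:.0f} Hz ({loaded.emg_di.units})")
print(f"Paw: {loaded.paw.n} samples at {loaded.paw.rate:.0f} Hz ({loaded.paw.units})")
print(f"PEEP schedule: {loaded.peep_schedule}")
print("\nSame thing from a shell:  nmcdi simulate --preset clean --seed 1 --out sess/")
print("                          nmcdi analyze --session sess/ --profile tolerant --out res/")
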