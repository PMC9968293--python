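# Dataset schema (version 1)

A cohort directory holds `trials.csv`, `srt.csv` and `meta.json`.

## trials.csv — main-task trials, one row per trial

| column            | type    | meaning |
|-------------------|---------|---------|
| participant_id    | str     | `P000`, `P001`, ... |
| session           | str     | `decision` or `movement` |
| condition         | str     | `fast` or `slow` |
| block_index       | int     | 0-based block position within the session |
| trial_id          | int     | 0-based trial position within the session |
| trial_type        | str     | `obvious`, `ambiguous`, `misleading`, `random` |
| winner            | str     | `left` or `right` (side that finishes longer) |
| steps             | str     | 179 characters of `L`/`R`: which banana each frame extended (`L` = −1, `R` = +1) |
| rt                | float   | first key press, ms from decision-phase onset; empty for no-response trials |
| choice            | str     | `left`, `right`, or `none` |
| decision_correct  | bool    | choice equals winner |
| commit_frame      | float   | generator ground truth: frame of accumulator commitment (empty without a response) |
| tap1 … tap4       | float   | the four inter-tap intervals, ms; empty when the movement phase had no taps |
| movement_correct  | bool    | four taps at the proper pace (timeout; snake constraints in the movement session) |
| frame_rate_ok     | bool    | false when the frame rate deviated ≥ 1 Hz from 60 Hz |
| premature_press   | bool    | key press during the pre-decision phase |

## srt.csv — simple-reaction-time trials

| column         | type  | meaning |
|----------------|-------|---------|
| participant_id | str   | as above |
| session        | str   | `decision` or `movement` |
| condition      | str   | `fast`, `slow`, or `none` (snake-free block of the decision session) |
| rt             | float | reaction time, ms |
| premature      | bool  | response before the go signal |

## meta.json

`schema_version`, the dataset `seed`, the full `config` (CohortConfig
fields), and `ground_truth`: per participant and session, the generative
bound, motor-delay mean and tap-interval mean per condition, sufficient to
recompute every planted group difference exactly.
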