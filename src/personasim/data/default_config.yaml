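# Default model constants.
#
# Every ordinal label (high/normal/low, long/med/short, ...) used by the
# per-category tables below resolves to a number in the `ordinal` section,
# so the whole parameterization is overridable without touching code.

ordinal:
  gain: {high: 2.0, normal: 1.0, low: 0.5}
  lability: {high: 0.03, normal: 0.01, low: 0.0}
  baseline: {positive: 0.3, zero: 0.0, negative: -0.3}
  au_amount: {high: 1.4, normal: 1.0, low: 0.6}
  filter_threshold: {high: 0.30, normal: 0.15, low: 0.05}
  duration_range:
    short: [0.5, 1.5]
    med: [1.5, 3.0]
    normal: [1.5, 3.0]
    long: [3.0, 6.0]
  avert_frequency: {high: 8.0, normal: 5.0, low: 3.0}   # idle-gaze re-decisions / min
  mutual_bias: {more_mutual: 0.7, both: 0.5, more_avert: 0.3}
  blink_factor: {high: 1.3, normal: 1.0, low: 0.8}
  head_speed: {high: 100.0, normal: 70.0, low: 40.0}    # deg/s
  idle_rate: {high: 6.0, normal: 4.0, low: 2.0}         # idle gestures / min
  speed_multiplier: {high: 1.6, normal: 1.0, low: 0.6}

# Extraversion x emotional-stability categories.  Each block names the
# ordinal label per dimension; numbers (posture-shift split) are literal.
affect:
  HELS: {baseline_valence: zero, gain_pos: high, gain_neg: high, lability: high,
         baseline_arousal: positive, arousal_gain: high}
  HEHS: {baseline_valence: positive, gain_pos: high, gain_neg: low, lability: low,
         baseline_arousal: negative, arousal_gain: low}
  LELS: {baseline_valence: negative, gain_pos: low, gain_neg: high, lability: high,
         baseline_arousal: positive, arousal_gain: high}
  LEHS: {baseline_valence: zero, gain_pos: low, gain_neg: low, lability: low,
         baseline_arousal: negative, arousal_gain: low}
  Neutral: {baseline_valence: zero, gain_pos: normal, gain_neg: normal, lability: low,
            baseline_arousal: zero, arousal_gain: normal}

face:
  HELS: {au_amount: high, filter_threshold: low, twitch: true}
  HEHS: {au_amount: high, filter_threshold: low, twitch: false}
  LELS: {au_amount: low, filter_threshold: high, twitch: true}
  LEHS: {au_amount: low, filter_threshold: high, twitch: false}
  Neutral: {au_amount: normal, filter_threshold: normal, twitch: false}

gaze:
  HELS: {mutual_bias: both, mutual_duration: long, avert_duration: short,
         avert_frequency: high, directions: [U, C, L, R], blink_factor: high,
         head_speed: high}
  HEHS: {mutual_bias: more_mutual, mutual_duration: long, avert_duration: med,
         avert_frequency: high, directions: [U, C, L, R], blink_factor: low,
         head_speed: high}
  LELS: {mutual_bias: more_avert, mutual_duration: short, avert_duration: short,
         avert_frequency: low, directions: [D, L, R], blink_factor: high,
         head_speed: low}
  LEHS: {mutual_bias: both, mutual_duration: short, avert_duration: med,
         avert_frequency: low, directions: [D, L, R, C], blink_factor: normal,
         head_speed: low}
  Neutral: {mutual_bias: both, mutual_duration: normal, avert_duration: normal,
            avert_frequency: normal, directions: [U, D, L, R, C],
            blink_factor: normal, head_speed: normal}

gesture:
  HELS: {idle_rate: high, lean: backward, posture_shift_prob: 0.10,
         posture_shift_speed: high, self_adaptor_speed: high, twitch: true,
         spacious: true}
  HEHS: {idle_rate: low, lean: forward, posture_shift_prob: 0.90,
         posture_shift_speed: high, self_adaptor_speed: high, twitch: false,
         spacious: true}
  LELS: {idle_rate: high, lean: backward, posture_shift_prob: 0.10,
         posture_shift_speed: low, self_adaptor_speed: low, twitch: true,
         spacious: false}
  LEHS: {idle_rate: low, lean: forward, posture_shift_prob: 0.90,
         posture_shift_speed: low, self_adaptor_speed: low, twitch: false,
         spacious: false}
  Neutral: {idle_rate: normal, lean: none, posture_shift_prob: 0.60,
            posture_shift_speed: normal, self_adaptor_speed: normal,
            twitch: false, spacious: false}

# Twitching is tied to low emotional stability (HELS/LELS).  Setting this
# true instead gives LEHS body twitches as one of the source tables prints.
gesture_options:
  table_literal_twitches: false
  body_twitch_rate_per_min: 2.0
  emblem_valence_max: -0.7
  emblem_arousal_min: 0.7
  wave_duration_s: 2.0

emotion_options:
  decay_rate: 0.05                 # 1/s relaxation toward baseline
  trigger_weights: {safety: 1.0, belonging: 0.6, esteem: 0.3}
  trigger_magnitudes:
    agent_win: 1.0
    agent_lose: 1.0
    user_wave: 1.0
    user_smile: 1.0
    space_invasion: 1.0
    enter_wait: 1.0
    approach_go: 0.05              # emitted once per tick while in Ready
    cycle_repeat_per_round: 0.2    # scaled by round index, capped at 1.0

face_options:
  twitch_rate_per_min: 2.0
  twitch_amplitude: 0.15
  twitch_duration_s: 0.2

gaze_options:
  saccade_mean_deg: 8.0
  saccade_max_deg: 60.0
  eye_limit_deg: 15.0
  blink_base_per_min: 11.6
  arousal_blink_gain: 0.5
  gui_bearing_deg: 35.0            # GUI monitor sits off to the agent's side
  user_hand_bearing_deg: 20.0      # looking down-forward at the user's hand

fsm_options:
  rounds: 5
  dwell: {Ready: 2.0, Go: 1.0, Hands: 1.5, Result: 2.0}
  still_speed: 0.1                 # m/s below which the user counts as standing still
  still_window: 0.5                # s

executive_options:
  defer_limit: 2.0
  attention_hold: 3.0

simulation_options:
  tick: 0.1
  personal_space_radius: 1.2
  neutral_band: 0.2
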