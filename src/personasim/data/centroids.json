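{
 "features": [
  "blink_rate",
  "mutual_gaze_fraction",
  "posture_shift_fraction",
  "idle_gesture_rate",
  "twitch_count",
  "mean_valence",
  "mean_arousal",
  "mean_au_intensity"
 ],
 "scale_mean": [
  13.04,
  0.626340230108044,
  0.4828261068996364,
  3.91,
  3.18,
  0.2897686425661248,
  -0.07523085355508458,
  0.33872603055555556
 ],
 "scale_std": [
  3.9212138895177517,
  0.28290540803518915,
  0.4075809911750105,
  2.1610891056245176,
  4.614484736972818,
  0.29577717225146916,
  0.24989556798987253,
  0.2589080985864079
 ],
 "centroids": {
  "HELS": [
   15.1,
   0.8577580769484007,
   0.08060897435897436,
   5.65,
   8.2,
   0.42477451531552013,
   0.16592662843140857,
   0.5813259027777777
  ],
  "HEHS": [
   9.6,
   0.7706112844210222,
   0.9357142857142857,
   2.5,
   0.0,
   0.6514680020715546,
   -0.30838320333067565,
   0.6523163888888888
  ],
  "LELS": [
   17.35,
   0.3148883062881201,
   0.09526759188523895,
   5.65,
   7.7,
   -0.144090882470085,
   0.17803922924177643,
   0.11248966666666664
  ],
  "LEHS": [
   11.55,
   0.5573476759031931,
   0.7666666666666667,
   1.25,
   0.0,
   0.16610202972334007,
   -0.33326117743224826,
   0.0167975
  ],
  "Neutral": [
   11.6,
   0.631095806979485,
   0.5358730158730158,
   4.5,
   0.0,
   0.35058954819029425,
   -0.07847574468568405,
   0.3307006944444444
  ]
 }
}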