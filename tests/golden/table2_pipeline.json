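{
 "closure": [
  [
   1.0,
   0.5448963039494866,
   0.7612292064869011,
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521
  ],
  [
   0.5448963039494866,
   1.0,
   0.5448963039494866,
   0.5448963039494866,
   0.6267620876413726,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866
  ],
  [
   0.7612292064869011,
   0.5448963039494866,
   1.0,
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521,
   0.5884253100490521
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   1.0,
   0.5448963039494866,
   0.6151629878439414,
   0.65928456504587,
   0.6151629878439414,
   0.6151629878439414,
   0.65928456504587
  ],
  [
   0.5448963039494866,
   0.6267620876413726,
   0.5448963039494866,
   0.5448963039494866,
   1.0,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866,
   0.5448963039494866
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.6151629878439414,
   0.5448963039494866,
   1.0,
   0.6151629878439414,
   0.720430167848823,
   0.6679178740800933,
   0.6151629878439414
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.65928456504587,
   0.5448963039494866,
   0.6151629878439414,
   1.0,
   0.6151629878439414,
   0.6151629878439414,
   0.6793028453745911
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.6151629878439414,
   0.5448963039494866,
   0.720430167848823,
   0.6151629878439414,
   1.0,
   0.6679178740800933,
   0.6151629878439414
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.6151629878439414,
   0.5448963039494866,
   0.6679178740800933,
   0.6151629878439414,
   0.6679178740800933,
   1.0,
   0.6151629878439414
  ],
  [
   0.5884253100490521,
   0.5448963039494866,
   0.5884253100490521,
   0.65928456504587,
   0.5448963039494866,
   0.6151629878439414,
   0.6793028453745911,
   0.6151629878439414,
   0.6151629878439414,
   1.0
  ]
 ],
 "subject_ids": [
  "A1",
  "A2",
  "A3",
  "A4",
  "A5",
  "A6",
  "A7",
  "A8",
  "A9",
  "A10"
 ],
 "lambda": 0.9,
 "clusters": [
  [
   "A1"
  ],
  [
   "A2"
  ],
  [
   "A3"
  ],
  [
   "A4"
  ],
  [
   "A5"
  ],
  [
   "A6"
  ],
  [
   "A7"
  ],
  [
   "A8"
  ],
  [
   "A9"
  ],
  [
   "A10"
  ]
 ],
 "shares": {
  "acute": 0.6779752288637587,
  "chronic": 0.3220247711362413
 },
 "q": {
  "A1": 5.966666666666667,
  "A2": 5.706666666666667,
  "A3": 5.538333333333334,
  "A4": 5.976666666666667,
  "A5": 5.045000000000001,
  "A6": 6.316666666666667,
  "A7": 6.2700000000000005,
  "A8": 6.7283333333333335,
  "A9": 7.260000000000001,
  "A10": 7.091666666666668
 },
 "taxonomy": {
  "M1": "acute",
  "M2": "acute",
  "M3": "acute",
  "M4": "chronic",
  "M5": "chronic",
  "M6": "acute"
 }
}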