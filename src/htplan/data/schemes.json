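[
 {
  "name": "detailed",
  "mapping": {
   "sat": "sat",
   "visceral_fat": "visceral_fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cancellous_bone",
   "bone_marrow": "bone_marrow",
   "bladder_wall": "bladder_wall",
   "urine": "urine",
   "small_intestine_wall": "small_intestine_wall",
   "small_intestine_lumen": "small_intestine_lumen",
   "large_intestine_wall": "large_intestine_wall",
   "large_intestine_lumen": "large_intestine_lumen",
   "gtv": "gtv"
  }
 },
 {
  "name": "clinical",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cortical_bone",
   "bone_marrow": "cortical_bone",
   "bladder_wall": "muscle",
   "urine": "muscle",
   "small_intestine_wall": "muscle",
   "small_intestine_lumen": "muscle",
   "large_intestine_wall": "muscle",
   "large_intestine_lumen": "muscle",
   "gtv": "gtv",
   "fat": "fat"
  }
 },
 {
  "name": "bone_type",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cancellous_bone",
   "bone_marrow": "bone_marrow",
   "bladder_wall": "muscle",
   "urine": "muscle",
   "small_intestine_wall": "muscle",
   "small_intestine_lumen": "muscle",
   "large_intestine_wall": "muscle",
   "large_intestine_lumen": "muscle",
   "gtv": "gtv",
   "fat": "fat"
  }
 },
 {
  "name": "bladder",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cortical_bone",
   "bone_marrow": "cortical_bone",
   "bladder_wall": "bladder_wall",
   "urine": "urine",
   "small_intestine_wall": "muscle",
   "small_intestine_lumen": "muscle",
   "large_intestine_wall": "muscle",
   "large_intestine_lumen": "muscle",
   "gtv": "gtv",
   "fat": "fat"
  }
 },
 {
  "name": "intestine",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cortical_bone",
   "bone_marrow": "cortical_bone",
   "bladder_wall": "muscle",
   "urine": "muscle",
   "small_intestine_wall": "small_intestine_wall",
   "small_intestine_lumen": "small_intestine_lumen",
   "large_intestine_wall": "large_intestine_wall",
   "large_intestine_lumen": "large_intestine_lumen",
   "gtv": "gtv",
   "fat": "fat"
  }
 },
 {
  "name": "bladder_and_intestine",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cortical_bone",
   "bone_marrow": "cortical_bone",
   "bladder_wall": "bladder_wall",
   "urine": "urine",
   "small_intestine_wall": "small_intestine_wall",
   "small_intestine_lumen": "small_intestine_lumen",
   "large_intestine_wall": "large_intestine_wall",
   "large_intestine_lumen": "large_intestine_lumen",
   "gtv": "gtv",
   "fat": "fat"
  }
 },
 {
  "name": "combined",
  "mapping": {
   "sat": "fat",
   "visceral_fat": "fat",
   "muscle": "muscle",
   "cortical_bone": "cortical_bone",
   "cancellous_bone": "cancellous_bone",
   "bone_marrow": "bone_marrow",
   "bladder_wall": "bladder_wall",
   "urine": "urine",
   "small_intestine_wall": "small_intestine_wall",
   "small_intestine_lumen": "small_intestine_lumen",
   "large_intestine_wall": "large_intestine_wall",
   "large_intestine_lumen": "large_intestine_lumen",
   "gtv": "gtv",
   "fat": "fat"
  }
 }
]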