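species,n_train,n_test,DenseNet201,Inception-ResNet-V2,InceptionV3,MobileNetV2,Xception,NASNetMobile,Ensemble
No Animal,8566,473,0.966,0.947,0.962,0.926,0.962,0.943,0.970
White-tailed Deer,7484,420,0.990,0.962,0.969,0.968,0.963,0.972,0.976
Elk,5426,309,0.987,0.968,0.974,0.977,0.977,0.974,0.981
Wolf,5269,246,0.955,0.939,0.935,0.967,0.963,0.971,0.967
Grizzly Bear,3803,211,0.986,0.976,0.962,0.981,0.986,0.986,0.995
Mule Deer,2785,158,0.962,0.949,0.918,0.930,0.956,0.949,0.968
Snowshoe Hare,2328,110,0.955,0.918,0.945,0.864,0.964,0.800,0.936
Bighorn Sheep,1050,57,0.965,1.0,0.982,1.0,1.0,1.0,1.0
Coyote,893,53,0.774,0.925,0.925,0.925,0.943,0.811,0.943
Lynx,854,45,0.956,0.956,0.956,0.978,0.933,0.844,0.956
Black Bear,761,34,0.971,0.853,0.941,0.912,0.941,0.529,0.971
Red Fox,688,36,0.750,0.778,0.694,0.722,0.861,0.778,0.806
Cougar,635,29,1.0,0.333,1.0,0.667,1.0,1.0,1.0
Moose,512,24,0.916,1.0,0.792,0.917,0.958,0.583,0.958
Canada Goose,461,31,1.0,1.0,1.0,1.0,1.0,1.0,1.0
Marten,223,10,0.600,0.700,0.700,0.700,0.900,0.700,0.700
Vehicle,199,8,1.0,0.750,1.0,0.875,1.0,1.0,1.0
Wolverine,187,11,0.812,0.722,0.812,0.812,0.812,0.636,0.812
Horse Rider,159,10,0.800,0.700,0.400,0.800,0.800,0.800,0.800
Hiker,153,8,1.0,0.375,0.750,0.875,0.750,0.625,1.0
Snowmobile,146,9,1.0,1.0,0.889,0.889,1.0,0.667,0.889
Dog,135,7,0.571,0.571,0.857,0.286,0.571,0.429,0.714
Horse,122,8,0.875,0.750,1.0,1.0,1.0,0.875,1.0
Mountain Goat,119,8,1.0,1.0,0.875,0.750,0.875,0.750,1.0
Bobcat,106,2,1.0,0.0,1.0,1.0,1.0,0.0,1.0
Skier,103,3,1.0,1.0,1.0,1.0,1.0,1.0,1.0
Porcupine,102,6,0.500,0.167,0.333,0.667,0.667,0.500,0.500
Marmot,101,8,0.750,0.500,0.750,0.625,0.875,0.875,0.750
Pika,101,3,1.0,1.0,1.0,1.0,0.667,1.0,1.0
Caribou,94,6,0.833,0.500,0.667,0.500,0.333,0.333,0.500
Indiscernable,87,9,0.889,0.111,0.889,0.889,0.556,0.889,1.0
Hunter,84,4,1.0,0.250,1.0,0.500,0.500,0.750,1.0
Ground Squirrel,79,3,0.333,0.0,0.0,0.333,0.333,0.0,0.0
Badger,75,6,1.0,0.667,0.500,0.667,0.833,0.500,0.833
River Otter,75,2,0.500,0.500,0.0,0.0,0.500,0.500,0.500
Raccoon,67,5,1.0,0.600,0.400,0.600,1.0,0.800,1.0
Snowshoer,65,5,1.0,0.0,0.600,0.600,0.400,0.600,0.800
Common Raven,64,3,1.0,0.333,0.667,0.333,1.0,1.0,1.0
Runner,60,1,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Bald Eagle,58,4,0.750,1.0,0.750,0.500,0.750,0.250,1.0
Beaver,57,3,0.667,0.667,0.667,0.333,0.333,0.667,0.667
Muskrat,57,2,0.0,0.0,0.500,0.500,0.500,0.500,0.500
Cattle,56,3,0.667,0.0,0.667,0.667,1.0,0.667,1.0
Grouse,49,2,1.0,1.0,1.0,1.0,1.0,1.0,1.0
Striped Skunk,48,5,0.600,0.800,1.0,0.600,0.800,0.600,0.800
Fisher,46,1,1.0,0.0,1.0,0.0,0.0,1.0,1.0
Chipmunk,42,4,0.500,0.500,0.500,0.250,0.500,0.500,0.500
Biker,41,3,0.333,0.0,0.333,0.667,0.333,0.667,0.333
Flying Squirrel,38,2,1.0,0.500,1.0,1.0,0.500,0.500,1.0
Mouse,31,1,1.0,1.0,0.0,1.0,0.0,1.0,1.0
Golden Eagle,30,1,1.0,1.0,1.0,1.0,1.0,1.0,1.0
Invertebrate,29,7,1.0,0.429,0.714,1.0,1.0,0.857,1.0
Red Squirrel,25,2,0.500,0.500,0.0,0.0,0.500,0.500,0.500
Small Bird,19,1,0.0,0.0,0.0,0.0,0.0,0.0,0.0
Woodrat,8,2,0.0,0.0,0.0,0.0,0.0,0.0,0.0
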